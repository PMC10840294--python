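"""Per-stage SSV threshold calibration and the four-stage decision rule.

The calibrated threshold for one stage is the quartile rule: the mean of
the 25th percentile of the rice samples' SSV values and the 75th
percentile of the non-rice samples' SSV values. Quantiles use linear
interpolation between order statistics (numpy's default; Hyndman-Fan
type 7), overridable through ``quantile_method``.

A pixel is rice iff its SSV meets the stage threshold (inclusive >=) at
*all four* stages:

    rice  <=>  SSV_sowing >= t1 and SSV_transplanting >= t2
               and SSV_growing >= t3 and SSV_maturity >= t4

The published reference thresholds are (0.98, 0.985, 0.99, 0.985).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid
from .ssv import CalibrationError, SSVImage
from .types import STAGES, SamplePointSet, SchemaError

logger = logging.getLogger("ricemap")

#: Published per-stage thresholds (sowing, transplanting, growing, maturity).
PAPER_DEFAULT_THRESHOLDS = (0.98, 0.985, 0.99, 0.985)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-stage scalar SSV thresholds."""

    sowing: float
    transplanting: float
    growing: float
    maturity: float
    provenance: str = "calibrated"

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.as_tuple())):
            raise ValueError("thresholds must be finite")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.sowing, self.transplanting, self.growing, self.maturity)

    @classmethod
    def paper_default(cls) -> "ThresholdSet":
        return cls(*PAPER_DEFAULT_THRESHOLDS, provenance="paper-default")


def select_threshold(
    rice_ssv, nonrice_ssv, quantile_method: str = "linear"
) -> float:
    """Quartile-rule threshold: (Q25(rice) + Q75(non-rice)) / 2."""
    rice = np.asarray(list(rice_ssv), dtype=np.float64)
    nonrice = np.asarray(list(nonrice_ssv), dtype=np.float64)
    if rice.size == 0 or nonrice.size == 0:
        raise CalibrationError("both rice and non-rice SSV samples are required")
    q_rice = float(np.percentile(rice, 25, method=quantile_method))
    q_non = float(np.percentile(nonrice, 75, method=quantile_method))
    if q_non >= q_rice:
        logger.warning(
            "rice and non-rice SSV distributions overlap at the quartiles "
            "(Q25 rice=%.6g <= Q75 non-rice=%.6g)", q_rice, q_non,
        )
    return (q_rice + q_non) / 2.0


def _sample_ssv(
    img: SSVImage, samples: SamplePointSet
) -> tuple[list[float], list[float]]:
    rice, nonrice = [], []
    h, w = img.grid.shape
    for (row, col), label in zip(samples.pixels(img.grid), samples.binary_labels):
        if not (0 <= row < h and 0 <= col < w):
            continue
        v = img.ssv[row, col]
        if not np.isfinite(v):
            continue
        (rice if label == "rice" else nonrice).append(float(v))
    return rice, nonrice


def calibrate_thresholds(
    ssv_images: dict[str, SSVImage],
    samples: SamplePointSet,
    quantile_method: str = "linear",
) -> tuple[ThresholdSet, dict[str, dict[str, list[float]]]]:
    """One quartile-rule threshold per stage from training samples.

    Returns the ThresholdSet plus the per-stage SSV values at the sample
    points (rice / non-rice), exportable as histogram data.
    """
    values: dict[str, dict[str, list[float]]] = {}
    thresholds = []
    for stage in STAGES:
        if stage not in ssv_images:
            raise SchemaError(f"missing SSV image for stage {stage!r}")
        rice, nonrice = _sample_ssv(ssv_images[stage], samples)
        if not rice or not nonrice:
            raise CalibrationError(
                f"stage {stage!r}: no valid {'rice' if not rice else 'non-rice'} "
                "training samples"
            )
        values[stage] = {"rice": rice, "non-rice": nonrice}
        thresholds.append(select_threshold(rice, nonrice, quantile_method))
    return ThresholdSet(*thresholds, provenance="calibrated"), values


@dataclass
class RiceMap:
    """Binary rice raster: 1 = rice, 0 = non-rice; invalid where any stage
    SSV is nodata."""

    values: np.ndarray  # uint8
    valid: np.ndarray   # bool
    grid: RasterGrid
    thresholds: ThresholdSet | None = None

    @property
    def rice_mask(self) -> np.ndarray:
        return (self.values == 1) & self.valid

    @property
    def rice_area_m2(self) -> float:
        return float(self.rice_mask.sum()) * self.grid.pixel_area


def classify(ssv_images: dict[str, SSVImage], thresholds: ThresholdSet) -> RiceMap:
    """Apply the four-stage decision rule.

    A pixel is rice iff every stage SSV meets its threshold (inclusive);
    a pixel with nodata SSV at any stage is invalid in the output.
    """
    missing = [s for s in STAGES if s not in ssv_images]
    if missing:
        raise SchemaError(f"missing SSV image(s) for stage(s) {missing}")
    grid = ssv_images[STAGES[0]].grid
    for stage in STAGES:
        grid.require_match(ssv_images[stage].grid, f"SSV image for {stage}")
    stack = np.stack([ssv_images[s].ssv for s in STAGES])
    valid = np.isfinite(stack).all(axis=0)
    t = np.asarray(thresholds.as_tuple())[:, None, None]
    with np.errstate(invalid="ignore"):
        rice = (stack >= t).all(axis=0) & valid
    return RiceMap(
        values=rice.astype(np.uint8), valid=valid, grid=grid, thresholds=thresholds,
    )
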