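"""Phenological-stage compositing.

Each acquisition is assigned to the phenological stage whose half-open
day-of-year window contains it; acquisitions outside all windows (fallow)
are excluded. Within a stage, the mean composite takes the per-pixel
arithmetic mean over all unmasked, non-nodata dates, producing one
representative multi-band image per stage. SAR backscatter in dB is
averaged directly in dB space, which is how stage-mean backscatter
trajectories are reported for this method; ascending and descending passes
are averaged together, which also damps terrain-induced intensity
anomalies.

Spectral indices are computed *after* compositing the reflectance bands,
so each stage contributes one feature image and one curve.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .features import DEFAULT_INDICES, compute_index
from .grid import RasterGrid
from .types import (
    CropCalendar,
    OPTICAL_BANDS,
    SAR_BANDS,
    SchemaError,
    TemporalStack,
)


class StageCoverageError(ValueError):
    """A phenological stage has no usable acquisitions."""


def assign_stage(date: _dt.date, calendar: CropCalendar) -> str | None:
    """Stage of an acquisition date, or None when it falls in fallow."""
    return calendar.stage_of(date)


def mean_composite(
    stack: TemporalStack,
    stage: str,
    calendar: CropCalendar,
    cloud_masks: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-band arithmetic mean over the stage's unmasked valid dates.

    cloud_masks, when given, is a boolean (n_dates, H, W) array aligned
    with the stack; True marks cloud-contaminated pixels to exclude. A
    pixel with zero valid dates in the stage comes out NaN.
    """
    idx = [i for i, d in enumerate(stack.dates) if assign_stage(d, calendar) == stage]
    if not idx:
        raise StageCoverageError(
            f"no acquisitions of kind {stack.kind!r} fall in stage {stage!r}"
        )
    vals = stack.values[idx].astype(np.float64, copy=True)  # (T, B, H, W)
    if cloud_masks is not None:
        vals[np.asarray(cloud_masks, dtype=bool)[idx, None, :, :].repeat(vals.shape[1], axis=1)] = np.nan
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(vals)
        count = valid.sum(axis=0)
        total = np.where(valid, vals, 0.0).sum(axis=0)
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return {band: mean[b] for b, band in enumerate(stack.bands)}


@dataclass
class StageFeatureImage:
    """One multi-band feature raster for one phenological stage.

    The feature order is identical across the four stages so that pixel
    feature vectors x and the standard curve y align index by index.
    """

    stage: str
    feature_names: list[str]
    values: np.ndarray  # (n_features, H, W), NaN = invalid
    grid: RasterGrid

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.feature_names), *self.grid.shape):
            raise SchemaError("feature image shape does not match declared features/grid")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values).all(axis=0)

    def vector_at(self, row: int, col: int) -> np.ndarray:
        return self.values[:, row, col]


def feature_list(mode: str, indices: tuple[str, ...] = DEFAULT_INDICES) -> list[str]:
    """Declared feature order for a sensor mode.

    combined: 10 reflectance bands + 6 indices + VH/VV + elevation/slope
    (20 layers); optical-only drops the SAR pair; sar-only keeps only
    VH/VV plus the terrain pair.
    """
    optical = list(OPTICAL_BANDS) + [i.lower() for i in indices]
    terrain = ["elevation", "slope"]
    if mode == "combined":
        return optical + list(SAR_BANDS) + terrain
    if mode == "optical-only":
        return optical + terrain
    if mode == "sar-only":
        return list(SAR_BANDS) + terrain
    raise ValueError(f"unknown sensor mode {mode!r}")


def build_stage_feature_image(
    stage: str,
    grid: RasterGrid,
    optical_composite: dict[str, np.ndarray] | None,
    sar_composite: dict[str, np.ndarray] | None,
    terrain: dict[str, np.ndarray],
    mode: str = "combined",
    indices: tuple[str, ...] = DEFAULT_INDICES,
) -> StageFeatureImage:
    """Stack composited reflectance, indices, SAR means and terrain layers.

    Indices are computed here, on the stage-composited reflectance.
    """
    names = feature_list(mode, indices)
    layers: dict[str, np.ndarray] = {}
    if mode != "sar-only":
        if optical_composite is None:
            raise SchemaError(f"mode {mode!r} requires an optical composite")
        layers.update(optical_composite)
        for ind in indices:
            layers[ind.lower()] = compute_index(optical_composite, ind)
    if mode != "optical-only":
        if sar_composite is None:
            raise SchemaError(f"mode {mode!r} requires a SAR composite")
        layers.update(sar_composite)
    layers.update(terrain)
    missing = [n for n in names if n not in layers]
    if missing:
        raise SchemaError(f"stage {stage}: missing source for feature(s) {missing}")
    values = np.stack([np.asarray(layers[n], dtype=np.float64) for n in names])
    return StageFeatureImage(stage=stage, feature_names=names, values=values, grid=grid)
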