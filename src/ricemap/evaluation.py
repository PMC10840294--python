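"""Accuracy assessment and patch-size / slope recognition analyses.

The confusion matrix is tabulated rice-first (rows = predicted
{rice, non-rice}, columns = reference). User accuracy is precision per
predicted class, producer accuracy recall per reference class, overall
accuracy the trace fraction, and kappa Cohen's chance-corrected agreement
from the marginals. Display rounding is half-up to two decimals (the
presentation used in published accuracy tables); unrounded values are
always available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
from skimage import measure

from .thresholds import RiceMap
from .types import SamplePointSet

logger = logging.getLogger("ricemap")


class EvaluationError(ValueError):
    """No usable reference data for an evaluation."""


def _round2(v) -> float:
    """Half-up display rounding to two decimals.

    Exact rationals are quantized exactly (0.775 -> 0.78); floats would
    misround such ties through their binary representation.
    """
    if isinstance(v, Fraction):
        d = Decimal(v.numerator) / Decimal(v.denominator)
    else:
        if not np.isfinite(v):
            return v
        d = Decimal(v)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """2x2 counts; rows predicted {rice, non-rice}, columns reference."""

    counts: np.ndarray
    dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AccuracyReport:
    ua_rice: float
    pa_rice: float
    ua_nonrice: float
    pa_nonrice: float
    oa: float
    kappa: float
    #: exact rational values (when computed from integer counts), used so
    #: that display rounding of ties like 31/40 = 0.775 is exact
    exact: dict = field(default_factory=dict, repr=False, compare=False)

    _FIELDS = ("ua_rice", "pa_rice", "ua_nonrice", "pa_nonrice", "oa", "kappa")

    def rounded(self) -> dict[str, float]:
        return {
            k: _round2(self.exact.get(k, getattr(self, k))) for k in self._FIELDS
        }

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


def confusion(pred: RiceMap, samples: SamplePointSet) -> ConfusionMatrix:
    """Tabulate predicted vs reference binary labels at sample points.

    Points on invalid (nodata) or out-of-grid pixels are dropped with a
    logged count; zero usable points is an error.
    """
    counts = np.zeros((2, 2), dtype=np.int64)
    dropped = 0
    h, w = pred.grid.shape
    for (row, col), ref in zip(samples.pixels(pred.grid), samples.binary_labels):
        if not (0 <= row < h and 0 <= col < w) or not pred.valid[row, col]:
            dropped += 1
            continue
        i = 0 if pred.values[row, col] == 1 else 1
        j = 0 if ref == "rice" else 1
        counts[i, j] += 1
    if dropped:
        logger.warning("evaluation: dropped %d sample(s) on invalid pixels", dropped)
    if counts.sum() == 0:
        raise EvaluationError("no usable validation points on valid predicted pixels")
    return ConfusionMatrix(counts, dropped=dropped)


def metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """UA/PA per class, overall accuracy and Cohen's kappa from a 2x2 matrix.

    Ratios with a zero marginal are reported as NaN (not applicable).
    """
    c = [[int(v) for v in row] for row in cm.counts]
    total = sum(map(sum, c))
    if total == 0:
        raise EvaluationError("empty confusion matrix")
    row = [sum(c[i]) for i in range(2)]
    col = [c[0][j] + c[1][j] for j in range(2)]

    def _ratio(num: int, den: int):
        return Fraction(num, den) if den > 0 else None

    oa = Fraction(c[0][0] + c[1][1], total)
    pe = Fraction(row[0] * col[0] + row[1] * col[1], total**2)
    kappa = (oa - pe) / (1 - pe) if pe < 1 else None
    exact = {
        "ua_rice": _ratio(c[0][0], row[0]),
        "pa_rice": _ratio(c[0][0], col[0]),
        "ua_nonrice": _ratio(c[1][1], row[1]),
        "pa_nonrice": _ratio(c[1][1], col[1]),
        "oa": oa,
        "kappa": kappa,
    }
    as_float = {k: float(v) if v is not None else float("nan") for k, v in exact.items()}
    return AccuracyReport(
        **as_float, exact={k: v for k, v in exact.items() if v is not None}
    )


def _bins_from_edges(edges: list[float]) -> list[tuple[float, float]]:
    edges = sorted(float(e) for e in edges)
    bounds = [0.0, *edges, float("inf")]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def patch_recognition_by_size(
    truth: np.ndarray,
    pred: RiceMap,
    bin_edges_m2: list[float] = (400.0, 800.0),
    connectivity: int = 2,
) -> dict[str, dict[str, float]]:
    """Recognized proportion of true rice pixels per patch-area bin.

    True-rice patches are connected components (8-connected by default;
    ``connectivity=1`` for 4-connected); a truth pixel counts as
    recognized when the prediction marks it rice. Each patch contributes
    its pixels to the bin its total area (pixels x pixel area) falls in;
    the proportion is recognized pixels / truth pixels over the bin's
    patches. Bins with no patches are omitted.
    """
    truth = np.asarray(truth).astype(bool)
    if truth.shape != pred.grid.shape:
        raise EvaluationError("truth raster is not on the prediction grid")
    if not truth.any():
        raise EvaluationError("truth raster contains no rice")
    labels = measure.label(truth, connectivity=connectivity)
    pixel_area = pred.grid.pixel_area
    recognized = truth & (pred.values == 1) & pred.valid
    out: dict[str, dict[str, float]] = {}
    patch_ids, patch_sizes = np.unique(labels[labels > 0], return_counts=True)
    rec_per_patch = np.bincount(
        labels[recognized], minlength=labels.max() + 1
    )
    for lo, hi in _bins_from_edges(list(bin_edges_m2)):
        in_bin = (patch_sizes * pixel_area >= lo) & (patch_sizes * pixel_area < hi)
        if not in_bin.any():
            continue
        tot = int(patch_sizes[in_bin].sum())
        rec = int(rec_per_patch[patch_ids[in_bin]].sum())
        key = f"[{lo:g}, {hi:g}) m2" if np.isfinite(hi) else f">= {lo:g} m2"
        out[key] = {
            "proportion": rec / tot,
            "patches": int(in_bin.sum()),
            "truth_pixels": tot,
            "recognized_pixels": rec,
        }
    return out


def recognition_by_slope(
    truth: np.ndarray,
    pred: RiceMap,
    slope: np.ndarray,
    bin_edges_deg: list[float] = (2.0, 6.0, 10.0),
) -> dict[str, dict[str, float]]:
    """Recognized / total true-rice pixel ratio per slope interval.

    Slope bins are half-open on sorted edges, starting at 0 degrees and
    ending open. Bins with no true rice are reported with a NaN ratio
    (not applicable).
    """
    truth = np.asarray(truth).astype(bool)
    slope = np.asarray(slope, dtype=np.float64)
    if truth.shape != pred.grid.shape or slope.shape != pred.grid.shape:
        raise EvaluationError("truth/slope rasters are not on the prediction grid")
    recognized = truth & (pred.values == 1) & pred.valid
    out: dict[str, dict[str, float]] = {}
    for lo, hi in _bins_from_edges(list(bin_edges_deg)):
        sel = truth & (slope >= lo) & (slope < hi)
        tot = int(sel.sum())
        rec = int((sel & recognized).sum())
        key = f"[{lo:g}, {hi:g}) deg" if np.isfinite(hi) else f">= {lo:g} deg"
        out[key] = {
            "ratio": rec / tot if tot else float("nan"),
            "truth_pixels": tot,
            "recognized_pixels": rec,
        }
    return out
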