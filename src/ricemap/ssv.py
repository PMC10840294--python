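"""Standard feature curves and the spectral similarity vector (SSV).

For each phenological stage the reference vector y — the rice standard
feature curve — is the per-feature mean over the rice training pixels of
that stage's composite. Every pixel's feature vector x is then scored
against y with

    d(x, y)      = sqrt(sum_i (x_i - y_i)^2)
    d_norm(x, y) = (d - d_min) / (d_max - d_min)
    CS(x, y)     = sum_i x_i y_i / (||x|| ||y||)
    SSV          = CS(x, y) - d_norm(x, y)

where d_min and d_max are the extremes of the Euclidean-distance image
over the stage's valid pixels. Rice-like pixels have CS near 1 and small
distance, so SSV concentrates near 1 for rice.

The distance normalization makes SSV scene-dependent: adding or removing
pixels can change d_min/d_max and therefore every score. This is inherent
to the definition and is documented rather than altered.

Because the raw features mix reflectance ([0, 1]), dB (tens), degrees and
nanometres (REP ~ 700), a per-feature min-max scaling over the stage's
valid pixels is applied by default before matching (the curve is
transformed with the identical record); without it the large-magnitude
features dominate both CS and d. ``none`` disables scaling for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .composite import StageFeatureImage
from .grid import RasterGrid
from .types import SamplePointSet, SchemaError

logger = logging.getLogger("ricemap")


class CalibrationError(ValueError):
    """Not enough usable sample points to build a curve or threshold."""


@dataclass
class StandardCurve:
    """Per-stage reference feature vector y (mean over rice training pixels)."""

    stage: str
    feature_names: list[str]
    values: np.ndarray
    sample_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.feature_names),):
            raise SchemaError("curve length does not match its feature list")


@dataclass
class ScalingRecord:
    """Per-feature affine ranges of a min-max scaling, reusable on vectors."""

    mode: str
    vmin: np.ndarray | None = None
    vmax: np.ndarray | None = None

    @property
    def degenerate(self) -> np.ndarray:
        """True where a feature band was constant (mapped to 0)."""
        if self.mode == "none":
            return np.zeros(0, dtype=bool)
        return self.vmax == self.vmin

    def apply_vector(self, v: np.ndarray) -> np.ndarray:
        if self.mode == "none":
            return np.asarray(v, dtype=np.float64)
        span = self.vmax - self.vmin
        out = np.where(span > 0, (v - self.vmin) / np.where(span > 0, span, 1.0), 0.0)
        return out


def scale_features(
    image: StageFeatureImage, mode: str = "minmax"
) -> tuple[StageFeatureImage, ScalingRecord]:
    """Min-max scale each feature band to [0, 1] over its valid pixels.

    A constant band maps to 0 everywhere and is flagged degenerate. Mode
    ``none`` is the identity.
    """
    if mode == "none":
        return image, ScalingRecord(mode="none")
    if mode != "minmax":
        raise ValueError(f"unknown scaling mode {mode!r}")
    vals = image.values
    with np.errstate(invalid="ignore"):
        vmin = np.nanmin(vals.reshape(vals.shape[0], -1), axis=1)
        vmax = np.nanmax(vals.reshape(vals.shape[0], -1), axis=1)
    record = ScalingRecord(mode="minmax", vmin=vmin, vmax=vmax)
    if record.degenerate.any():
        degen = [image.feature_names[i] for i in np.nonzero(record.degenerate)[0]]
        logger.warning("stage %s: degenerate constant feature band(s) %s", image.stage, degen)
    span = (vmax - vmin)[:, None, None]
    scaled = np.where(span > 0, (vals - vmin[:, None, None]) / np.where(span > 0, span, 1.0), 0.0)
    scaled = np.where(np.isfinite(vals), scaled, np.nan)
    return (
        StageFeatureImage(image.stage, list(image.feature_names), scaled, image.grid),
        record,
    )


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two equal-length feature vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise SchemaError(f"feature vectors have different lengths: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of the angle between x and y, clipped to [-1, 1].

    A zero-norm vector has no direction; the result is NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise SchemaError(f"feature vectors have different lengths: {x.shape} vs {y.shape}")
    nx = np.sqrt(np.sum(x**2))
    ny = np.sqrt(np.sum(y**2))
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.clip(np.sum(x * y) / (nx * ny), -1.0, 1.0))


def normalize_distance(d: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Min-max normalize a distance image over its valid pixels.

    Returns (d_norm, d_min, d_max). A constant-distance image normalizes
    to 0 everywhere (degenerate); an all-NaN image is an error.
    """
    d = np.asarray(d, dtype=np.float64)
    finite = np.isfinite(d)
    if not finite.any():
        raise CalibrationError("distance image has no valid pixels")
    d_min = float(np.nanmin(d))
    d_max = float(np.nanmax(d))
    if d_max == d_min:
        logger.warning("degenerate distance image (constant %.6g); d_norm set to 0", d_min)
        d_norm = np.where(finite, 0.0, np.nan)
    else:
        d_norm = (d - d_min) / (d_max - d_min)
    return d_norm, d_min, d_max


@dataclass
class SSVImage:
    """Per-stage spectral-similarity score raster with its components."""

    stage: str
    ssv: np.ndarray
    cs: np.ndarray
    d: np.ndarray
    d_norm: np.ndarray
    d_min: float
    d_max: float
    grid: RasterGrid


def build_standard_curve(
    image: StageFeatureImage, rice_points: SamplePointSet
) -> StandardCurve:
    """Mean feature vector over rice training pixels (the curve y).

    Points landing on invalid (NaN-feature) pixels are dropped with a
    logged count; zero usable points is a calibration error.
    """
    rice = rice_points.subset("rice")
    if len(rice) == 0:
        raise CalibrationError(f"stage {image.stage}: no rice points supplied")
    valid = image.valid_mask
    vectors = []
    dropped = 0
    for row, col in rice.pixels(image.grid):
        if 0 <= row < image.grid.height and 0 <= col < image.grid.width and valid[row, col]:
            vectors.append(image.values[:, row, col])
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "stage %s: %d rice point(s) on invalid pixels excluded from the curve",
            image.stage, dropped,
        )
    if not vectors:
        raise CalibrationError(
            f"stage {image.stage}: no rice training point falls on a valid pixel"
        )
    return StandardCurve(
        stage=image.stage,
        feature_names=list(image.feature_names),
        values=np.mean(vectors, axis=0),
        sample_count=len(vectors),
    )


def ssv_image(
    image: StageFeatureImage,
    curve: StandardCurve,
    scaling: str = "minmax",
) -> SSVImage:
    """Score every pixel of a stage against the rice standard curve.

    Applies feature scaling (curve transformed with the same record),
    computes per-pixel cosine similarity and Euclidean distance to the
    curve, normalizes the distance over the whole valid image, and returns
    SSV = CS - d_norm. Pixels with any NaN feature, and zero-norm pixels
    under cosine, come out NaN.
    """
    if list(curve.feature_names) != list(image.feature_names):
        raise SchemaError(
            f"curve features {curve.feature_names} do not match image features "
            f"{image.feature_names}"
        )
    scaled, record = scale_features(image, scaling)
    y = record.apply_vector(curve.values)
    vals = scaled.values  # (F, H, W)
    valid = np.isfinite(vals).all(axis=0)

    diff = vals - y[:, None, None]
    d = np.sqrt(np.sum(diff**2, axis=0))
    d[~valid] = np.nan

    ny = np.sqrt(np.sum(y**2))
    if ny == 0.0:
        raise CalibrationError(f"stage {image.stage}: scaled standard curve has zero norm")
    nx = np.sqrt(np.sum(vals**2, axis=0))
    dot = np.sum(vals * y[:, None, None], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where(nx > 0, dot / (nx * ny), np.nan)
    cs = np.clip(cs, -1.0, 1.0)
    cs[~valid] = np.nan
    n_zero = int((valid & (nx == 0)).sum())
    if n_zero:
        logger.warning("stage %s: %d zero-norm pixel(s) left as nodata", image.stage, n_zero)

    d_norm, d_min, d_max = normalize_distance(d)
    ssv = cs - d_norm
    return SSVImage(
        stage=image.stage, ssv=ssv, cs=cs, d=d, d_norm=d_norm,
        d_min=d_min, d_max=d_max, grid=image.grid,
    )


def ssv_naive(
    image: StageFeatureImage, curve: StandardCurve, scaling: str = "minmax"
) -> np.ndarray:
    """Reference double-loop SSV used as an independent oracle in tests."""
    scaled, record = scale_features(image, scaling)
    y = record.apply_vector(curve.values)
    h, w = image.grid.shape
    d = np.full((h, w), np.nan)
    cs = np.full((h, w), np.nan)
    for r in range(h):
        for c in range(w):
            x = scaled.values[:, r, c]
            if not np.isfinite(x).all():
                continue
            d[r, c] = euclidean_distance(x, y)
            cs[r, c] = cosine_similarity(x, y)
    d_norm, _, _ = normalize_distance(d)
    return cs - d_norm
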