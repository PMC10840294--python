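"""Optical spectral indices, cloud scoring and terrain features.

The feature set follows the rice feature dataset of the method: the ten
surface-reflectance bands, six spectral indices (NDVI, NDWI, NDREI, REP,
MTCI and a soil/moisture NDSI), the two SAR backscatter channels (VH, VV)
and two terrain layers (elevation, slope). Index formulas are the standard
Sentinel-2 definitions for these index names; each is registered in
``INDEX_FORMULAS`` and can be overridden or extended.

Notation: R665 = red, R705 = first red-edge band (re1), R740 = re2,
R783 = re3.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import SchemaError


def _nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Normalized difference (a-b)/(a+b); zero denominator -> NaN."""
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    return out


def _ratio(num: np.ndarray, denom: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom != 0, num / denom, np.nan)


INDEX_FORMULAS = {
    "ndvi": lambda b: _nd(b["nir"], b["red"]),
    "ndwi": lambda b: _nd(b["green"], b["nir"]),
    "ndrei": lambda b: _nd(b["nir"], b["re1"]),
    # Red-edge position (Guyot-Baret linear interpolation), in nm.
    "rep": lambda b: 705.0
    + 35.0 * _ratio(0.5 * (b["re3"] + b["red"]) - b["re1"], b["re2"] - b["re1"]),
    "mtci": lambda b: _ratio(b["re2"] - b["re1"], b["re1"] - b["red"]),
    # Soil/moisture-sensitive normalized difference on SWIR1 vs NIR.
    "ndsi": lambda b: _nd(b["swir1"], b["nir"]),
}

DEFAULT_INDICES = ("ndvi", "ndwi", "ndrei", "rep", "mtci", "ndsi")

#: Indices bounded in [-1, 1] by construction.
NORMALIZED_DIFFERENCE_INDICES = ("ndvi", "ndwi", "ndrei", "ndsi")


def compute_index(reflectance: dict[str, np.ndarray], name: str) -> np.ndarray:
    """Compute one spectral index from per-band reflectance rasters.

    NaN in any required band propagates; zero denominators yield NaN at the
    affected pixels. Normalized-difference indices are clipped to [-1, 1]
    (they can only leave that range through rounding).
    """
    key = name.lower()
    if key not in INDEX_FORMULAS:
        raise SchemaError(
            f"unknown index {name!r}; supported: {', '.join(sorted(INDEX_FORMULAS))}"
        )
    bands = {k: np.asarray(v, dtype=np.float64) for k, v in reflectance.items()}
    out = INDEX_FORMULAS[key](bands)
    if key in NORMALIZED_DIFFERENCE_INDICES:
        out = np.clip(out, -1.0, 1.0)
    return out


#: Rescale breakpoints of the simple cloud score: each term maps a
#: brightness (or snow-index) value linearly onto [0, 1] between (lo, hi).
CLOUD_SCORE_TERMS = {
    "blue": (0.1, 0.3),
    "visible_sum": (0.2, 0.8),       # blue + green + red
    "infrared_sum": (0.3, 0.8),      # nir + swir1 + swir2
    "snow_index": (0.8, 0.6),        # NDSI(snow) = (green - swir1)/(green + swir1), inverted
}

CLOUD_THRESHOLD = 0.3


def _rescale(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def cloud_score(
    reflectance: dict[str, np.ndarray],
    terms: dict | None = None,
    threshold: float = CLOUD_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Simple cloud score in [0, 1] plus the boolean cloud mask (score > 0.3).

    The score is the minimum of rescaled cloudiness indicators — blue-band
    brightness, total visible brightness, total infrared brightness, and an
    inverted snow index that keeps bright snow from scoring as cloud. A
    pixel is masked only when the score strictly exceeds the threshold.
    NaN in any contributing band propagates to the score and leaves the
    pixel unmasked (nodata, not cloud).
    """
    t = dict(CLOUD_SCORE_TERMS)
    if terms:
        t.update(terms)
    required = ("blue", "green", "red", "nir", "swir1", "swir2")
    missing = [b for b in required if b not in reflectance]
    if missing:
        raise SchemaError(f"cloud score requires bands {missing}")
    b = {k: np.asarray(reflectance[k], dtype=np.float64) for k in required}
    snow = _nd(b["green"], b["swir1"])
    score = np.minimum.reduce([
        _rescale(b["blue"], *t["blue"]),
        _rescale(b["blue"] + b["green"] + b["red"], *t["visible_sum"]),
        _rescale(b["nir"] + b["swir1"] + b["swir2"], *t["infrared_sum"]),
        _rescale(snow, *t["snow_index"]),
    ])
    invalid = np.zeros(score.shape, dtype=bool)
    for k in required:
        invalid |= ~np.isfinite(b[k])
    score = np.where(invalid, np.nan, score)
    mask = np.where(invalid, False, score > threshold)
    return score, mask


def compute_slope(dem: np.ndarray, pixel_size: float) -> np.ndarray:
    """Slope in degrees by Horn's 3x3 finite-difference method.

    Borders are handled by edge replication; any NaN inside a pixel's 3x3
    window makes the output NaN there (nodata is propagated, never
    interpolated).
    """
    dem = np.asarray(dem, dtype=np.float64)
    if dem.ndim != 2:
        raise SchemaError("DEM must be a single 2-D raster")
    z = np.pad(dem, 1, mode="edge")
    # 3x3 neighbourhood views: rows a b c / d e f / g h i, x east, y south
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * pixel_size)
    gy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * pixel_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    # NaN anywhere in the 8-neighbourhood invalidates the pixel.
    bad = ndimage.maximum_filter(~np.isfinite(dem) * 1.0, size=3, mode="nearest") > 0
    slope[bad] = np.nan
    return slope
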