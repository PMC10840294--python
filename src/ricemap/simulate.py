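"""Synthetic multi-temporal scene generator.

Generates fully self-contained test scenes with the statistical structure
the identification method assumes: a labelled class map (rice paddies of
controlled sizes over water / built-up / natural-vegetation / dry-land
background), a DEM with hills and a regional tilt, per-date 10-band
optical reflectance and VH/VV backscatter in dB drawn from class- and
stage-specific mean trajectories plus Gaussian noise, and bright
rectangular cloud blobs on optical dates.

The default rice trajectory follows the qualitative phenology of
single-season paddy rice: during sowing and transplanting the flooded
field is water-dominated (low reflectance everywhere, water indices high,
VH below -20 dB), through the growing period the canopy closes (NIR and
red-edge reflectance peak, VH climbs to about -15 dB), and at maturity
the canopy senesces (vegetation indices and backscatter decline). The
background classes are an always-wet water body, spectrally stable bright
built-up surfaces, evergreen natural vegetation with high but static
NIR, and rainfed dry-land cropland that greens up in summer but is never
flooded in spring — the confusion sources the four-stage rule exists to
reject.

Two resolution effects of real 10 m imagery are emulated. First, field
geometry is generated on a supersampled grid and does not align with the
sensor grid, so each coarse pixel's signal is the area-weighted mixture
of the classes in its footprint; a 200 m² terrace rarely fills any 10 m
pixel, while a 3000 m² field has pure interior pixels. Second, a light
3x3 point-spread blur mixes each pixel with its neighbours. Together
these make sub-400 m² paddies genuinely hard for the classifier, as they
are for the real sensors. Field size and terrain are coupled the way
hilly landscapes are: large consolidated fields sit on flat valley
floors, small fragments on steeper, higher ground.
"""

from __future__ import annotations

import datetime as _dt
import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import compute_slope
from .grid import RasterGrid
from .types import CropCalendar, OPTICAL_BANDS, SamplePointSet, STAGES, TemporalStack

CLASSES = ("rice", "water", "built-up", "natural-vegetation", "dry-land")

_CHANNELS = (*OPTICAL_BANDS, "vh", "vv")

# class, stage, blue..swir2 reflectance, VH dB, VV dB — editable tabular
# asset; values are plausibility-anchored to the qualitative trajectories
# above, not read off any instrument.
_DEFAULT_TRAJECTORIES_CSV = """\
class,stage,blue,green,red,re1,re2,re3,nir,nnir,swir1,swir2,vh,vv
rice,sowing,0.060,0.080,0.070,0.070,0.070,0.070,0.060,0.060,0.050,0.040,-21.0,-13.0
rice,transplanting,0.050,0.070,0.050,0.060,0.070,0.080,0.090,0.090,0.060,0.050,-23.0,-15.0
rice,growing,0.030,0.060,0.035,0.090,0.250,0.380,0.420,0.440,0.150,0.070,-15.0,-10.0
rice,maturity,0.050,0.080,0.090,0.130,0.220,0.280,0.300,0.310,0.220,0.130,-18.0,-12.0
water,sowing,0.050,0.060,0.040,0.035,0.030,0.030,0.025,0.025,0.015,0.010,-27.0,-19.0
water,transplanting,0.050,0.060,0.040,0.035,0.030,0.030,0.025,0.025,0.015,0.010,-27.0,-19.0
water,growing,0.050,0.060,0.040,0.035,0.030,0.030,0.025,0.025,0.015,0.010,-26.5,-18.5
water,maturity,0.050,0.060,0.040,0.035,0.030,0.030,0.025,0.025,0.015,0.010,-27.0,-19.0
built-up,sowing,0.140,0.160,0.180,0.190,0.200,0.210,0.220,0.220,0.240,0.220,-10.0,-4.0
built-up,transplanting,0.140,0.160,0.180,0.190,0.200,0.210,0.220,0.220,0.240,0.220,-10.0,-4.0
built-up,growing,0.140,0.160,0.180,0.190,0.200,0.210,0.220,0.220,0.240,0.220,-9.5,-4.0
built-up,maturity,0.140,0.160,0.180,0.190,0.200,0.210,0.220,0.220,0.240,0.220,-10.0,-4.0
natural-vegetation,sowing,0.035,0.070,0.045,0.080,0.200,0.300,0.320,0.330,0.160,0.080,-15.0,-9.0
natural-vegetation,transplanting,0.035,0.070,0.045,0.080,0.210,0.310,0.340,0.350,0.160,0.080,-14.5,-9.0
natural-vegetation,growing,0.035,0.070,0.040,0.085,0.230,0.340,0.380,0.390,0.190,0.095,-12.5,-7.5
natural-vegetation,maturity,0.035,0.070,0.045,0.080,0.220,0.320,0.360,0.370,0.155,0.080,-14.5,-9.0
dry-land,sowing,0.090,0.110,0.130,0.150,0.170,0.180,0.190,0.200,0.260,0.220,-19.0,-11.0
dry-land,transplanting,0.080,0.100,0.100,0.130,0.170,0.200,0.240,0.250,0.240,0.200,-17.5,-10.0
dry-land,growing,0.040,0.070,0.050,0.100,0.220,0.320,0.360,0.370,0.220,0.130,-13.0,-8.0
dry-land,maturity,0.080,0.100,0.120,0.150,0.190,0.220,0.250,0.260,0.250,0.210,-16.5,-9.5
"""


def default_trajectories() -> pd.DataFrame:
    """Class x stage mean trajectory table (long on class/stage)."""
    return pd.read_csv(_io.StringIO(_DEFAULT_TRAJECTORIES_CSV))


def trajectories_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"class", "stage", *(_CHANNELS)} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    return df


class GenerationError(RuntimeError):
    """The configured scene cannot be laid out on the grid."""


class SamplingError(ValueError):
    """A class has fewer free pixels than requested sample points."""


@dataclass
class SceneConfig:
    """Study conditions for one synthetic scene.

    The defaults describe the reference desk-scale scene: a 256x256 grid
    at 10 m, about 30 rice paddies spanning 200-3000 m² (so both sub-400 m²
    fragments and medium fields occur), three acquisitions per stage for
    each sensor, moderate sensor noise (larger for SAR, mimicking residual
    speckle), 10% cloud cover per optical date, and a hilly DEM.
    """

    size: int = 256
    pixel_size: float = 10.0
    n_rice_patches: int = 30
    rice_patch_area_m2: tuple[float, float] = (200.0, 3000.0)
    dem_base: float = 300.0
    dem_hill_amplitude: float = 120.0
    dem_tilt: float = 0.01
    optical_noise_sd: float = 0.015
    sar_noise_sd: float = 1.2
    cloud_fraction: float = 0.10
    cloud_reflectance: float = 0.55
    max_rice_slope: float = 12.0       # degrees; no paddies on steeper ground
    rice_slope_scale: float = 2.0      # e-folding of seed probability vs slope
    rice_valley_scale: float = 40.0    # m; e-folding of seed probability vs height above valley floor
    dates_per_stage: int = 3
    year: int = 2020
    psf: bool = True
    supersample: int = 2               # fine-grid factor for sub-pixel field geometry
    calendar: CropCalendar = field(default_factory=CropCalendar)
    trajectories: pd.DataFrame = field(default_factory=default_trajectories)
    background_fractions: dict = field(
        default_factory=lambda: {
            "dry-land": 0.35, "natural-vegetation": 0.35,
            "built-up": 0.15, "water": 0.15,
        }
    )
    seed: int = 0


@dataclass
class TruthScene:
    """A generated scene: truth class map plus everything the pipeline reads.

    ``class_map`` is the sensor-resolution truth (majority class of each
    pixel's footprint); ``class_map_fine`` is the supersampled field
    geometry it was derived from, and ``rice_fraction`` the sub-pixel
    rice cover of each coarse pixel.
    """

    class_map: np.ndarray           # int codes into CLASSES, (H, W)
    class_map_fine: np.ndarray      # (H*ss, W*ss)
    rice_fraction: np.ndarray       # (H, W) in [0, 1]
    dem: np.ndarray
    optical: TemporalStack
    sar: TemporalStack
    cloud_truth: np.ndarray         # (n_optical_dates, H, W) bool
    grid: RasterGrid
    config: SceneConfig

    @property
    def rice_mask(self) -> np.ndarray:
        return self.class_map == CLASSES.index("rice")

    def class_mask(self, name: str) -> np.ndarray:
        return self.class_map == CLASSES.index(name)


# three-by-three PSF: half of the signal from the pixel itself, half from
# its neighbours — a coarse stand-in for the sensor response at 10 m
_PSF = np.array([[1.0, 2.0, 1.0], [2.0, 12.0, 2.0], [1.0, 2.0, 1.0]]) / 24.0


def _stage_dates(calendar: CropCalendar, per_stage: int, year: int) -> list[_dt.date]:
    base = _dt.date(year, 1, 1)
    dates = []
    for _, start, end in calendar.stages:
        # evenly placed inside the half-open window, away from the edges
        doys = np.linspace(start + 2, end - 3, per_stage)
        dates.extend(base + _dt.timedelta(days=int(round(d)) - 1) for d in doys)
    return sorted(set(dates))


def _grow_patch(
    rng: np.random.Generator,
    free: np.ndarray,
    n_pixels: int,
    seed_weights: np.ndarray | None = None,
    max_tries: int = 200,
) -> np.ndarray | None:
    """Region-grow one connected blob of exactly n_pixels inside `free`."""
    h, w = free.shape
    free_idx = np.flatnonzero(free)
    if free_idx.size == 0:
        return None
    if seed_weights is not None:
        p = seed_weights.ravel()[free_idx]
        p = p / p.sum() if p.sum() > 0 else None
    else:
        p = None
    for _ in range(max_tries):
        seed = rng.choice(free_idx, p=p)
        r0, c0 = divmod(int(seed), w)
        patch = {(r0, c0)}
        frontier = [(r0, c0)]
        while len(patch) < n_pixels and frontier:
            r, c = frontier[rng.integers(len(frontier))]
            nbrs = [
                (r + dr, c + dc)
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < h and 0 <= c + dc < w
                and free[r + dr, c + dc] and (r + dr, c + dc) not in patch
            ]
            if not nbrs:
                frontier.remove((r, c))
                continue
            nxt = nbrs[rng.integers(len(nbrs))]
            patch.add(nxt)
            frontier.append(nxt)
        if len(patch) == n_pixels:
            mask = np.zeros_like(free)
            rows, cols = zip(*patch)
            mask[list(rows), list(cols)] = True
            return mask
    return None


def _make_class_map(
    cfg: SceneConfig,
    rng: np.random.Generator,
    slope: np.ndarray | None = None,
    dem: np.ndarray | None = None,
) -> np.ndarray:
    """Fine-grid (supersampled) class map: fields do not align with the
    sensor grid, so coarse pixels are class mixtures."""
    ss = cfg.supersample
    h = w = cfg.size * ss
    sub_area = (cfg.pixel_size / ss) ** 2
    # background: nearest-seed (Voronoi) regions over the non-rice classes
    names = list(cfg.background_fractions)
    probs = np.array([cfg.background_fractions[n] for n in names], dtype=float)
    probs /= probs.sum()
    n_seeds = max(8, (h * w) // (2000 * ss * ss))
    seeds = rng.integers(0, [h, w], size=(n_seeds, 2))
    seed_class = rng.choice(len(names), size=n_seeds, p=probs)
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr[None] - seeds[:, 0, None, None]) ** 2 + (cc[None] - seeds[:, 1, None, None]) ** 2
    nearest = d2.argmin(axis=0)
    class_map = np.array(
        [CLASSES.index(names[k]) for k in seed_class], dtype=np.int8
    )[nearest]

    # rice paddies stamped on top, pairwise non-adjacent (8-conn separation)
    # paddies must hold standing water, so fields concentrate on gentle
    # terrain in valley bottoms and flat dams: seeds are drawn with
    # probability falling off exponentially in slope and in height above
    # the valley floor, and growth is confined below `max_rice_slope`.
    # Field areas are log-uniform (right-skewed, as real field-size
    # inventories are), so sub-400 m² fragments genuinely occur.
    lo, hi = cfg.rice_patch_area_m2
    if hi < sub_area or cfg.n_rice_patches == 0:
        return class_map  # rice fraction zero
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_rice_patches))
    sizes = np.maximum(1, np.round(areas / sub_area)).astype(int)
    rice_code = CLASSES.index("rice")
    rice_all = np.zeros((h, w), dtype=bool)
    if slope is None:
        terrain_ok = np.ones((h, w), dtype=bool)
    else:
        terrain_ok = slope < cfg.max_rice_slope
        above_floor = (
            np.maximum(dem - np.percentile(dem, 5), 0.0)
            if dem is not None else np.zeros((h, w))
        )
    # field size and terrain are coupled, as in real hilly landscapes:
    # large consolidated fields occupy flat valley floors, while small
    # fragments are terraces carved into steeper, higher ground. Each
    # patch therefore targets a slope band that falls with its area.
    sep = np.ones((2 * ss + 1, 2 * ss + 1))  # keep distinct fields ≥1 coarse px apart
    for n_px, area in zip(sizes, areas):
        free = terrain_ok & ~ndimage.binary_dilation(rice_all, sep)
        if slope is None:
            weights = None
        else:
            s_target = max(0.3, 5.0 - 1.5 * np.log(area / 100.0))
            weights = np.exp(-0.5 * ((slope - s_target) / cfg.rice_slope_scale) ** 2)
            sharp = max(1.0, np.sqrt(area / 800.0))
            weights = weights * np.exp(-above_floor * sharp / cfg.rice_valley_scale)
        patch = _grow_patch(rng, free, int(n_px), seed_weights=weights)
        if patch is None:
            raise GenerationError(
                f"could not place a {n_px}-pixel rice patch on the {h}x{w} grid"
            )
        rice_all |= patch
    class_map[rice_all] = rice_code
    return class_map


def _make_dem(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h = w = cfg.size
    x = np.arange(w) * cfg.pixel_size
    y = np.arange(h) * cfg.pixel_size
    xx, yy = np.meshgrid(x, y)
    dem = cfg.dem_base + cfg.dem_tilt * xx
    for _ in range(2):
        cx, cy = rng.uniform(0, w * cfg.pixel_size), rng.uniform(0, h * cfg.pixel_size)
        sigma = rng.uniform(0.12, 0.25) * w * cfg.pixel_size
        dem += cfg.dem_hill_amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
        )
    return dem


def _cloud_mask(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Random rectangular cloud blobs covering about cloud_fraction."""
    h = w = cfg.size
    mask = np.zeros((h, w), dtype=bool)
    target = cfg.cloud_fraction * h * w
    guard = 0
    while mask.sum() < target and guard < 100:
        guard += 1
        ch = int(rng.integers(h // 16, h // 4 + 1))
        cw = int(rng.integers(w // 16, w // 4 + 1))
        r = int(rng.integers(0, h - ch + 1))
        c = int(rng.integers(0, w - cw + 1))
        mask[r : r + ch, c : c + cw] = True
    return mask


def generate_scene(config: SceneConfig | None = None, seed: int | None = None) -> TruthScene:
    """Generate a reproducible TruthScene from a SceneConfig.

    The same config and seed always give a bit-identical scene.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h = w = cfg.size
    grid = RasterGrid(
        width=w, height=h,
        transform=(500000.0, cfg.pixel_size, 0.0, 3400000.0, 0.0, -cfg.pixel_size),
    )
    dem = _make_dem(cfg, rng)
    slope = compute_slope(dem, cfg.pixel_size)
    ss = cfg.supersample
    slope_f = np.repeat(np.repeat(slope, ss, axis=0), ss, axis=1)
    dem_f = np.repeat(np.repeat(dem, ss, axis=0), ss, axis=1)
    class_fine = _make_class_map(cfg, rng, slope_f, dem_f)

    traj = cfg.trajectories.set_index(["class", "stage"])
    present = np.unique(class_fine)
    missing = [
        (c, s) for c in present for s in STAGES
        if (CLASSES[c], s) not in traj.index
    ]
    if missing:
        raise GenerationError(f"trajectory table lacks entries for {missing}")

    # per-coarse-pixel class cover fractions (the sub-pixel mixture weights)
    fractions = {
        code: (class_fine == code).reshape(h, ss, w, ss).mean(axis=(1, 3))
        for code in present
    }
    rice_code = CLASSES.index("rice")
    rice_fraction = fractions.get(rice_code, np.zeros((h, w)))
    # coarse truth: majority class; rice wins at exactly half cover
    frac_stack = np.stack([fractions[c] for c in present])
    class_map = np.asarray(present, dtype=np.int8)[frac_stack.argmax(axis=0)]
    class_map[rice_fraction >= 0.5] = rice_code

    def mean_image(stage: str, channels: tuple[str, ...]) -> np.ndarray:
        out = np.zeros((len(channels), h, w))
        for code in present:
            row = traj.loc[(CLASSES[code], stage)]
            vals = np.array([row[ch] for ch in channels])
            out += vals[:, None, None] * fractions[code][None]
        if cfg.psf:
            for i in range(len(channels)):
                out[i] = ndimage.convolve(out[i], _PSF, mode="nearest")
        return out

    opt_dates = _stage_dates(cfg.calendar, cfg.dates_per_stage, cfg.year)
    sar_dates = [d + _dt.timedelta(days=1) for d in opt_dates]

    optical = np.empty((len(opt_dates), len(OPTICAL_BANDS), h, w))
    cloud_truth = np.zeros((len(opt_dates), h, w), dtype=bool)
    sar = np.empty((len(sar_dates), 2, h, w))
    stage_mean_opt: dict[str, np.ndarray] = {}
    stage_mean_sar: dict[str, np.ndarray] = {}
    for t, date in enumerate(opt_dates):
        stage = cfg.calendar.stage_of(date)
        if stage not in stage_mean_opt:
            stage_mean_opt[stage] = mean_image(stage, OPTICAL_BANDS)
            stage_mean_sar[stage] = mean_image(stage, ("vh", "vv"))
        img = stage_mean_opt[stage] + rng.normal(
            0.0, cfg.optical_noise_sd, size=(len(OPTICAL_BANDS), h, w)
        )
        if cfg.cloud_fraction > 0:
            cm = _cloud_mask(cfg, rng)
            cloud_truth[t] = cm
            cloud_vals = cfg.cloud_reflectance + rng.normal(0.0, 0.03, size=(len(OPTICAL_BANDS), h, w))
            img = np.where(cm[None], cloud_vals, img)
        optical[t] = np.clip(img, 0.0, 1.0)
        sar[t] = stage_mean_sar[stage] + rng.normal(0.0, cfg.sar_noise_sd, size=(2, h, w))

    optical_stack = TemporalStack(
        dates=opt_dates, bands=list(OPTICAL_BANDS), values=optical,
        grid=grid, kind="optical-reflectance",
    )
    sar_stack = TemporalStack(
        dates=sar_dates, bands=["vh", "vv"], values=np.clip(sar, -59.0, 19.0),
        grid=grid, kind="sar-db",
    )
    return TruthScene(
        class_map=class_map, class_map_fine=class_fine, rice_fraction=rice_fraction,
        dem=dem, optical=optical_stack, sar=sar_stack,
        cloud_truth=cloud_truth, grid=grid, config=cfg,
    )


def sample_points(
    truth: TruthScene,
    n_per_class: dict[str, int],
    role: str = "training",
    seed: int = 0,
    training_counts: dict[str, int] | None = None,
) -> SamplePointSet:
    """Draw per-class sample points uniformly without replacement.

    Training and validation draws from the same seed are disjoint: one
    seeded permutation of each class's pixels is made, training points
    come from its front and validation points from its back. Points sit
    at pixel centres.
    """
    rng = np.random.default_rng(seed)
    points: list[tuple[float, float, str]] = []
    order = {}
    for cls in CLASSES:  # fixed iteration order for determinism
        pix = np.flatnonzero(truth.class_map == CLASSES.index(cls))
        order[cls] = rng.permutation(pix)
    for cls, n in n_per_class.items():
        if cls not in CLASSES:
            raise SamplingError(f"unknown class {cls!r}")
        perm = order[cls]
        if n > perm.size:
            raise SamplingError(
                f"requested {n} {cls} points but only {perm.size} pixels exist"
            )
        if role == "training":
            chosen = perm[:n]
        else:
            n_train = (training_counts or {}).get(cls, 0)
            if n_train + n > perm.size:
                raise SamplingError(
                    f"class {cls}: training ({n_train}) + validation ({n}) exceed "
                    f"{perm.size} available pixels"
                )
            chosen = perm[perm.size - n :]
        w = truth.grid.width
        for idx in chosen:
            r, c = divmod(int(idx), w)
            x, y = truth.grid.xy_of(r, c)
            points.append((x, y, cls))
    return SamplePointSet(points, role=role)


#: Sample sizes mirroring a realistic field campaign in one county:
#: 75 rice + 288 non-rice training points, 65 rice + 121 non-rice validation.
DEFAULT_TRAINING_COUNTS = {
    "rice": 75, "water": 72, "built-up": 72, "natural-vegetation": 72, "dry-land": 72,
}
DEFAULT_VALIDATION_COUNTS = {
    "rice": 65, "water": 30, "built-up": 30, "natural-vegetation": 30, "dry-land": 31,
}
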