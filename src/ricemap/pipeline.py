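"""End-to-end orchestration: composites -> features -> curves -> SSV ->
thresholds -> classification -> evaluation.

`identify_rice` is the in-memory core; `run_pipeline` is the file-based
wrapper driven by a YAML config (the `simulate` CLI writes a ready-made
one). Both are pure functions of their inputs: two runs on the same
inputs produce identical rasters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .composite import StageFeatureImage, build_stage_feature_image, mean_composite
from .features import DEFAULT_INDICES, cloud_score, compute_slope
from .ssv import SSVImage, StandardCurve, build_standard_curve, ssv_image
from .thresholds import RiceMap, ThresholdSet, calibrate_thresholds, classify
from .evaluation import confusion, metrics
from .types import CropCalendar, SamplePointSet, STAGES, TemporalStack

logger = logging.getLogger("ricemap")

MODES = ("combined", "optical-only", "sar-only")


class ConfigError(ValueError):
    """The pipeline configuration is incomplete or inconsistent."""


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RiceResult:
    """Everything one identification run produces."""

    rice_map: RiceMap
    ssv_images: dict[str, SSVImage]
    stage_images: dict[str, StageFeatureImage]
    curves: dict[str, StandardCurve]
    thresholds: ThresholdSet
    threshold_samples: dict | None
    cloud_masks: np.ndarray | None
    slope: np.ndarray | None
    report: dict = field(default_factory=dict)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageFailure(name, exc) from exc


def identify_rice(
    optical: TemporalStack | None,
    sar: TemporalStack | None,
    dem: np.ndarray,
    calendar: CropCalendar,
    training_samples: SamplePointSet,
    mode: str = "combined",
    scaling: str = "minmax",
    thresholds: str | ThresholdSet = "calibrate",
    indices: tuple[str, ...] = DEFAULT_INDICES,
) -> RiceResult:
    """Run the identification method in memory.

    ``thresholds`` is "calibrate" (quartile rule on the training samples),
    "paper" (the published defaults) or an explicit ThresholdSet.
    """
    if mode not in MODES:
        raise ConfigError(f"sensor mode must be one of {MODES}, got {mode!r}")
    use_optical = mode != "sar-only"
    use_sar = mode != "optical-only"
    if use_optical and optical is None:
        raise ConfigError(f"mode {mode!r} requires an optical stack")
    if use_sar and sar is None:
        raise ConfigError(f"mode {mode!r} requires a SAR stack")
    ref = optical if use_optical else sar
    grid = ref.grid
    dem = np.asarray(dem, dtype=np.float64)
    if dem.shape != grid.shape:
        raise ConfigError("DEM is not on the pipeline grid")
    if use_optical and use_sar:
        grid.require_match(sar.grid, "SAR stack")

    report: dict = {"mode": mode, "scaling": scaling}
    if not use_optical:
        report["skipped"] = "optical feature stages skipped (sar-only mode)"
    if not use_sar:
        report["skipped"] = "SAR feature stages skipped (optical-only mode)"

    cloud_masks = None
    if use_optical:
        def _clouds():
            masks = np.zeros((optical.n_dates, *grid.shape), dtype=bool)
            for t in range(optical.n_dates):
                bands = {b: optical.values[t, i] for i, b in enumerate(optical.bands)}
                _, masks[t] = cloud_score(bands)
            return masks
        cloud_masks = _stage("cloud-mask", _clouds)
        report["cloud_fraction_mean"] = float(cloud_masks.mean())

    slope = _stage("terrain", compute_slope, dem, grid.pixel_size)
    terrain = {"elevation": dem, "slope": slope}

    stage_images: dict[str, StageFeatureImage] = {}
    for stage in STAGES:
        opt_comp = (
            _stage(f"composite:{stage}", mean_composite, optical, stage, calendar, cloud_masks)
            if use_optical else None
        )
        sar_comp = (
            _stage(f"composite:{stage}", mean_composite, sar, stage, calendar, None)
            if use_sar else None
        )
        stage_images[stage] = _stage(
            f"features:{stage}", build_stage_feature_image,
            stage, grid, opt_comp, sar_comp, terrain, mode, indices,
        )

    curves = {
        stage: _stage(f"curve:{stage}", build_standard_curve, img, training_samples)
        for stage, img in stage_images.items()
    }
    ssv_images = {
        stage: _stage(f"ssv:{stage}", ssv_image, img, curves[stage], scaling)
        for stage, img in stage_images.items()
    }

    threshold_samples = None
    if isinstance(thresholds, ThresholdSet):
        tset = thresholds
    elif thresholds == "paper":
        tset = ThresholdSet.paper_default()
    elif thresholds == "calibrate":
        tset, threshold_samples = _stage(
            "thresholds", calibrate_thresholds, ssv_images, training_samples
        )
    else:
        raise ConfigError(
            f"thresholds must be 'calibrate', 'paper' or a ThresholdSet, got {thresholds!r}"
        )
    report["thresholds"] = dict(zip(STAGES, tset.as_tuple()))
    report["thresholds_provenance"] = tset.provenance

    rice_map = _stage("classify", classify, ssv_images, tset)
    report["rice_pixels"] = int(rice_map.rice_mask.sum())
    report["rice_area_m2"] = rice_map.rice_area_m2
    return RiceResult(
        rice_map=rice_map, ssv_images=ssv_images, stage_images=stage_images,
        curves=curves, thresholds=tset, threshold_samples=threshold_samples,
        cloud_masks=cloud_masks, slope=slope, report=report,
    )


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise ConfigError(f"config is missing required key {key!r}")
    return cfg[key]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RiceResult:
    """Execute the full pipeline from a config file or dict.

    The config names the input rasters, calendar, samples and options;
    outputs (rice map, per-stage SSV rasters, thresholds, metrics report)
    are written under ``output.dir`` unless ``out_dir`` overrides it.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    mode = config.get("mode", "combined")
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}")
    calendar = CropCalendar.from_dict(_require(config, "calendar"))
    inputs = _require(config, "inputs")

    optical = sar = None
    if mode != "sar-only":
        o = _require(inputs, "optical")
        optical = rio.read_stack(o["paths"], o["dates"], "optical-reflectance")
    if mode != "optical-only":
        s = _require(inputs, "sar")
        sar = rio.read_stack(s["paths"], s["dates"], "sar-db")
    dem_values, dem_grid, _, _ = rio.read_raster(_require(inputs, "dem"))
    grid = (optical or sar).grid
    grid.require_match(dem_grid, "DEM")

    samples_cfg = _require(config, "samples")
    training = rio.read_samples(_require(samples_cfg, "training"), grid, role="training")

    thresholds_cfg = config.get("thresholds", "calibrate")
    if isinstance(thresholds_cfg, (list, tuple)):
        thresholds = ThresholdSet(*[float(t) for t in thresholds_cfg], provenance="user")
    else:
        thresholds = thresholds_cfg

    result = identify_rice(
        optical, sar, dem_values[0], calendar, training,
        mode=mode, scaling=config.get("scaling", "minmax"), thresholds=thresholds,
        indices=tuple(config.get("indices", DEFAULT_INDICES)),
    )

    if "validation" in samples_cfg:
        validation = rio.read_samples(samples_cfg["validation"], grid, role="validation")
        cm = _stage("evaluate", confusion, result.rice_map, validation)
        rep = metrics(cm)
        result.report["confusion"] = cm.counts.tolist()
        result.report["accuracy"] = rep.to_dict()
        result.report["accuracy_rounded"] = rep.rounded()

    out = Path(out_dir or config.get("output", {}).get("dir", "ricemap_output"))
    out.mkdir(parents=True, exist_ok=True)
    rio.write_raster(
        out / "rice_map.tif",
        np.where(result.rice_map.valid, result.rice_map.values, 255).astype(np.uint8),
        grid, ["rice"], extra_meta={"nodata": 255},
    )
    for stage, img in result.ssv_images.items():
        rio.write_raster(
            out / f"ssv_{stage}.tif",
            np.stack([img.ssv, img.cs, img.d, img.d_norm]).astype(np.float32),
            grid, ["ssv", "cs", "d", "d_norm"],
            extra_meta={"d_min": img.d_min, "d_max": img.d_max},
        )
    pd.DataFrame(
        [(s, v) for s, v in result.report["thresholds"].items()],
        columns=["stage", "threshold"],
    ).to_csv(out / "thresholds.csv", index=False)
    for stage, curve in result.curves.items():
        pd.DataFrame(
            {"feature": curve.feature_names, "value": curve.values}
        ).to_csv(out / f"curve_{stage}.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
    logger.info("pipeline outputs written to %s", out)
    return result
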