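"""GeoTIFF raster and sample-point I/O.

Rasters are GeoTIFFs written through :mod:`tifffile`; georeferencing
(GDAL-style transform, CRS, nodata) plus band names, dates and any extra
metadata travel as a JSON document in the TIFF ImageDescription tag, so a
write-then-read round-trip preserves values, nodata and georeferencing
exactly. Sample points come from CSV (columns x, y, label) or GeoJSON
point features with a ``label`` property.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import GridAlignmentError, RasterGrid
from .types import SamplePointSet, SchemaError, TemporalStack

logger = logging.getLogger("ricemap")

_META_KEY = "ricemap"


def write_raster(
    path: str | Path,
    values: np.ndarray,
    grid: RasterGrid,
    band_names: list[str] | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write a (bands, H, W) or (H, W) array as a georeferenced TIFF."""
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None]
    if values.shape[1:] != grid.shape:
        raise SchemaError(f"array shape {values.shape} does not match grid {grid.shape}")
    meta = {
        _META_KEY: True,
        "transform": list(grid.transform),
        "crs": grid.crs,
        "nodata": None if np.isnan(grid.nodata) else grid.nodata,
        "band_names": band_names or [f"band_{i + 1}" for i in range(values.shape[0])],
    }
    if extra_meta:
        meta.update(extra_meta)
    tifffile.imwrite(
        Path(path),
        values,
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, RasterGrid, list[str], dict]:
    """Read a TIFF written by :func:`write_raster`.

    Returns (values (bands, H, W), grid, band_names, metadata).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if values.ndim == 2:
        values = values[None]
    nodata = meta.get("nodata")
    grid = RasterGrid(
        width=values.shape[2],
        height=values.shape[1],
        transform=tuple(meta.get("transform", (0.0, 10.0, 0.0, 0.0, 0.0, -10.0))),
        crs=meta.get("crs", "unknown"),
        nodata=float("nan") if nodata is None else float(nodata),
    )
    band_names = meta.get("band_names", [f"band_{i + 1}" for i in range(values.shape[0])])
    return values, grid, band_names, meta


def read_stack(
    paths: list[str | Path],
    dates: list[_dt.date | str],
    kind: str,
    bands: list[str] | None = None,
) -> TemporalStack:
    """Assemble per-date rasters into a validated TemporalStack.

    All files must already sit on one grid; a mismatch raises
    GridAlignmentError naming the offending file (no resampling).
    """
    if len(paths) != len(dates):
        raise ValueError("one acquisition date per file is required")
    parsed_dates = [
        d if isinstance(d, _dt.date) else _dt.date.fromisoformat(str(d)) for d in dates
    ]
    order = np.argsort(parsed_dates)
    layers, ref_grid, ref_bands = [], None, None
    for i in order:
        values, grid, band_names, _ = read_raster(paths[i])
        if ref_grid is None:
            ref_grid, ref_bands = grid, band_names
        else:
            try:
                ref_grid.require_match(grid)
            except GridAlignmentError as exc:
                raise GridAlignmentError(f"{paths[i]}: {exc}") from exc
            if band_names != ref_bands:
                raise SchemaError(
                    f"{paths[i]}: bands {band_names} differ from first file's {ref_bands}"
                )
        layers.append(values)
    if bands is not None:
        missing = [b for b in bands if b not in (ref_bands or [])]
        if missing:
            raise SchemaError(f"stack is missing declared bands {missing}")
        idx = [ref_bands.index(b) for b in bands]
        layers = [layer[idx] for layer in layers]
        ref_bands = list(bands)
    return TemporalStack(
        dates=[parsed_dates[i] for i in order],
        bands=list(ref_bands or []),
        values=np.stack(layers),
        grid=ref_grid,
        kind=kind,
    )


def write_stack(stack: TemporalStack, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, date in enumerate(stack.dates):
        p = out_dir / f"{date.isoformat()}.tif"
        write_raster(p, stack.values[i], stack.grid, band_names=list(stack.bands),
                     extra_meta={"date": date.isoformat(), "kind": stack.kind})
        paths.append(p)
    return paths


def read_samples(path: str | Path, grid: RasterGrid, role: str = "training") -> SamplePointSet:
    """Read labelled points from CSV (x,y,label) or GeoJSON point features.

    Points outside the grid extent are dropped with a logged count; an
    unknown label raises VocabularyError.
    """
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        with open(path) as fh:
            gj = json.load(fh)
        records = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise SchemaError(f"{path}: only Point features are supported")
            x, y = geom["coordinates"][:2]
            records.append((float(x), float(y), str(feat["properties"]["label"])))
    else:
        df = pd.read_csv(path)
        missing = {"x", "y", "label"} - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        records = [
            (float(r.x), float(r.y), str(r.label)) for r in df.itertuples(index=False)
        ]
    inside = [r for r in records if grid.contains(r[0], r[1])]
    dropped = len(records) - len(inside)
    if dropped:
        logger.warning("%s: dropped %d point(s) outside the grid extent", path, dropped)
    if not inside:
        logger.warning("%s: no usable sample points", path)
    return SamplePointSet(inside, role=role, dropped_outside=dropped)


def write_samples(samples: SamplePointSet, path: str | Path) -> None:
    pd.DataFrame(samples.points, columns=["x", "y", "label"]).to_csv(path, index=False)
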