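"""Raster and sample I/O.

Rasters are written as plain multiband TIFF with a JSON sidecar carrying
the grid metadata (pixel size, origin, band or layer names); point
samples go to CSV or GeoJSON. The sidecar convention keeps the files
readable by any TIFF-capable tool while preserving the georeferencing the
pipeline needs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import BAND_NAMES, ClassMap, FeatureStack, MonthlySeries


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(path, array, pixel_size: float, origin=(0.0, 0.0),
                 names=None, **extra) -> None:
    path = Path(path)
    array = np.asarray(array)
    tifffile.imwrite(path, array)
    meta = {"pixel_size": pixel_size, "origin": list(origin),
            "shape": list(array.shape)}
    if names is not None:
        meta["names"] = list(names)
    meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_raster(path):
    path = Path(path)
    array = tifffile.imread(path)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return array, meta


def write_series(directory, series: MonthlySeries) -> None:
    """One 5-band TIFF per month (4 spectral bands + validity)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in range(series.n_months):
        stack = np.concatenate([
            series.data[m],
            series.valid[m][None].astype(np.float32),
        ])
        write_raster(directory / f"month_{int(series.months[m]):02d}.tif",
                     stack, series.pixel_size, series.origin,
                     names=list(series.band_names) + ["valid"],
                     month=int(series.months[m]))


def read_series(directory) -> MonthlySeries:
    directory = Path(directory)
    paths = sorted(directory.glob("month_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no month_*.tif rasters in {directory}")
    data, months, valid = [], [], []
    pixel_size, origin = 1.0, (0.0, 0.0)
    for p in paths:
        arr, meta = read_raster(p)
        data.append(arr[:-1])
        valid.append(arr[-1] > 0.5)
        months.append(meta.get("month", len(months) + 1))
        pixel_size = meta.get("pixel_size", pixel_size)
        origin = tuple(meta.get("origin", origin))
    return MonthlySeries(np.stack(data), np.asarray(months), np.stack(valid),
                         band_names=BAND_NAMES, pixel_size=pixel_size,
                         origin=origin)


def write_class_map(path, class_map: ClassMap) -> None:
    write_raster(path, class_map.codes.astype(np.uint8),
                 class_map.pixel_size, class_map.origin,
                 proportions={str(k): v
                              for k, v in class_map.proportions.items()})


def read_class_map(path) -> ClassMap:
    arr, meta = read_raster(path)
    return ClassMap(arr, pixel_size=meta.get("pixel_size", 1.0),
                    origin=tuple(meta.get("origin", (0.0, 0.0))))


def write_feature_stack(path, stack: FeatureStack) -> None:
    write_raster(path, stack.data.astype(np.float32), stack.pixel_size,
                 stack.origin, names=stack.names)


def read_feature_stack(path) -> FeatureStack:
    arr, meta = read_raster(path)
    names = meta.get("names", [f"layer_{i}" for i in range(arr.shape[0])])
    return FeatureStack(names, arr, pixel_size=meta.get("pixel_size", 1.0),
                        origin=tuple(meta.get("origin", (0.0, 0.0))))


def write_samples_csv(path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, index=False)


def write_samples_geojson(path, samples: pd.DataFrame) -> None:
    features = []
    for _, s in samples.iterrows():
        props = {k: (v.item() if hasattr(v, "item") else v)
                 for k, v in s.items() if k not in ("x", "y")}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(s["x"]), float(s["y"])]},
            "properties": props,
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))
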