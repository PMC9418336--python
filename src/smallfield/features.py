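"""Classification feature stack: seasonal spectral metrics, radial-kernel
texture indices, contrast indices, terrain and coordinate layers.

Seasonal metrics are per-pixel percentiles over the valid observations of
each 4-month window: P50 of green, red, NIR and NDVI, plus P75 of NDVI
(the higher percentile captures the green peak of cropping cycles while
the median suppresses residual clouds). Texture indices (TI) are focal
medians of the seasonal NDVI P50 within radial kernels of 25, 100 and
200 m — radii bracketing typical smallholder field extents — computed for
the first and third season. Contrast indices normalize each pixel against
its TI neighborhood, CI = (P50 - TI) / (P50 + TI), which highlights fields
against their surroundings. Percentiles use linear interpolation between
order statistics throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (DEFAULT_PIXEL_SIZE, SEASON_WINDOWS, FeatureStack,
                   MonthlySeries, pixel_centers)

KERNEL_RADII_M = (25.0, 100.0, 200.0)
TEXTURE_SEASONS = (0, 2)  # first and third seasonal window


@dataclass
class SeasonalMetrics:
    """Per-season percentile composites keyed ``s{season}_{band}_{metric}``."""

    layers: dict[str, np.ndarray]
    pixel_size: float

    def __getitem__(self, key: str) -> np.ndarray:
        return self.layers[key]


def seasonal_metrics(series: MonthlySeries,
                     season_windows=SEASON_WINDOWS) -> SeasonalMetrics:
    """P50 of green/red/NIR/NDVI and P75 of NDVI per season window.

    Percentiles run over valid observations only; pixels with no valid
    observation in a window are NaN.
    """
    if any(len(w) != 4 for w in season_windows) or len(season_windows) != 3:
        raise ValueError("expected three 4-month season windows")
    ndvi = series.ndvi(masked=True)
    layers: dict[str, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s, window in enumerate(season_windows):
            idx = list(window)
            for band in ("green", "red", "nir"):
                arr = series.band(band).astype(np.float64)
                arr = np.where(series.valid, arr, np.nan)
                layers[f"s{s + 1}_{band}_p50"] = np.nanmedian(arr[idx], axis=0)
            block = ndvi[idx]
            layers[f"s{s + 1}_ndvi_p50"] = np.nanmedian(block, axis=0)
            layers[f"s{s + 1}_ndvi_p75"] = np.nanpercentile(block, 75, axis=0)
    return SeasonalMetrics(layers, series.pixel_size)


def _disk_offsets(radius_px: float) -> np.ndarray:
    """Boolean disk footprint: pixel centers within ``radius_px``."""
    r = int(np.floor(radius_px))
    yy, xx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1),
                         indexing="ij")
    return (yy ** 2 + xx ** 2) <= radius_px ** 2 + 1e-9


def focal_median(raster: np.ndarray, radius_px: float,
                 chunk_rows: int = 16) -> np.ndarray:
    """NaN-aware focal median over a circular kernel, truncated at edges.

    Implemented as a chunked sliding-window nanmedian over a NaN-padded
    array, so border pixels see exactly the in-grid part of the kernel.
    """
    if radius_px < 1:
        return raster.copy()
    footprint = _disk_offsets(radius_px)
    r = footprint.shape[0] // 2
    h, w = raster.shape
    padded = np.pad(raster.astype(np.float32), r, mode="constant",
                    constant_values=np.nan)
    flat = footprint.ravel()
    out = np.empty((h, w), dtype=np.float64)
    win = footprint.shape[0]
    view = np.lib.stride_tricks.sliding_window_view(padded, (win, win))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for r0 in range(0, h, chunk_rows):
            r1 = min(r0 + chunk_rows, h)
            block = view[r0:r1].reshape(r1 - r0, w, win * win)[:, :, flat]
            out[r0:r1] = np.nanmedian(block, axis=2)
    return out


def texture_index(p50_ndvi: np.ndarray, radius_m: float,
                  pixel_size_m: float = DEFAULT_PIXEL_SIZE) -> np.ndarray:
    """Focal median of a seasonal NDVI composite within a radial kernel."""
    if radius_m < pixel_size_m:
        return p50_ndvi.copy()
    return focal_median(p50_ndvi, radius_m / pixel_size_m)


def contrast_index(p50_ndvi: np.ndarray, ti: np.ndarray) -> np.ndarray:
    """Normalized difference (P50 - TI)/(P50 + TI); 0 where the sum is 0."""
    if p50_ndvi.shape != ti.shape:
        raise ValueError("grids differ")
    denom = p50_ndvi + ti
    out = np.zeros_like(denom, dtype=np.float64)
    ok = np.abs(denom) > 1e-12
    out[ok] = (p50_ndvi[ok] - ti[ok]) / denom[ok]
    return out


def terrain_features(dem: np.ndarray,
                     pixel_size_m: float = DEFAULT_PIXEL_SIZE
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Elevation passthrough and slope in degrees via central differences."""
    dzdy, dzdx = np.gradient(dem.astype(np.float64), pixel_size_m)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.astype(np.float64), slope


def coordinate_features(shape, pixel_size_m: float = DEFAULT_PIXEL_SIZE,
                        origin=(0.0, 0.0)) -> tuple[np.ndarray, np.ndarray]:
    """Latitude-like (y/north) and longitude-like (x/east) pixel-center
    layers in the scene coordinate system."""
    y, x = pixel_centers(shape, pixel_size_m, origin)
    return y, x


def assemble_stack(series: MonthlySeries, dem: np.ndarray,
                   season_windows=SEASON_WINDOWS,
                   kernel_radii_m=KERNEL_RADII_M,
                   texture_seasons=TEXTURE_SEASONS) -> FeatureStack:
    """Full default stack: 15 seasonal metrics + 6 TI + 6 CI + elevation,
    slope, latitude, longitude = 31 layers, in a fixed documented order."""
    metrics = seasonal_metrics(series, season_windows)
    names: list[str] = []
    layers: list[np.ndarray] = []
    for s in range(1, 4):
        for band in ("green", "red", "nir"):
            names.append(f"s{s}_{band}_p50")
            layers.append(metrics[f"s{s}_{band}_p50"])
        names.append(f"s{s}_ndvi_p50")
        layers.append(metrics[f"s{s}_ndvi_p50"])
        names.append(f"s{s}_ndvi_p75")
        layers.append(metrics[f"s{s}_ndvi_p75"])
    px = series.pixel_size
    ti_layers: dict[str, np.ndarray] = {}
    for s in texture_seasons:
        p50 = metrics[f"s{s + 1}_ndvi_p50"]
        for radius in kernel_radii_m:
            key = f"s{s + 1}_ti_{int(radius)}m"
            ti_layers[key] = texture_index(p50, radius, px)
            names.append(key)
            layers.append(ti_layers[key])
    for s in texture_seasons:
        p50 = metrics[f"s{s + 1}_ndvi_p50"]
        for radius in kernel_radii_m:
            names.append(f"s{s + 1}_ci_{int(radius)}m")
            layers.append(contrast_index(p50, ti_layers[f"s{s + 1}_ti_{int(radius)}m"]))
    elev, slope = terrain_features(dem, px)
    lat, lon = coordinate_features(series.shape, px, series.origin)
    names += ["elevation", "slope", "latitude", "longitude"]
    layers += [elev, slope, lat, lon]
    return FeatureStack(names, np.stack(layers), pixel_size=px,
                        origin=series.origin)
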