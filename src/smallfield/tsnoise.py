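"""Multi-temporal consistency metric for NDVI time series.

For every triplet of consecutive valid observations (y_i, y_i+1, y_i+2)
acquired at integer month positions, the center value is compared with the
linear interpolation between the two outer values; the statistic is the
mean of the squared deviations,

    TSNoise = 1/(N-2) * sum_i ( y_{i+1} - [ y_i + (y_{i+2} - y_i) *
              (month_{i+1} - month_i) / (month_{i+2} - month_i) ] )^2

with N the number of valid observations. Residual misregistration moves
field edges between months and inflates the statistic there, which makes
the map of TSNoise a cheap QA layer for coregistration. Missing months
shrink the triplet set (no imputation); unequal spacing enters through the
month terms. Undefined (NaN) where N < 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MonthlySeries


def ts_noise(y, months=None, root: bool = False) -> float:
    """Time-series noise of a single series.

    Parameters
    ----------
    y : array-like
        Valid observations, in time order.
    months : array-like, optional
        Strictly increasing integer month positions; defaults to 1..N.
    root : bool
        Return the square root of the statistic (NDVI units instead of
        NDVI^2); off by default.
    """
    y = np.asarray(y, dtype=np.float64)
    if months is None:
        months = np.arange(1, y.size + 1)
    months = np.asarray(months, dtype=np.float64)
    if months.shape != y.shape:
        raise ValueError("months must align with observations")
    if np.any(np.diff(months) <= 0):
        raise ValueError("months must be strictly increasing")
    n = y.size
    if n < 3:
        return float("nan")
    y0, y1, y2 = y[:-2], y[1:-1], y[2:]
    m0, m1, m2 = months[:-2], months[1:-1], months[2:]
    pred = y0 + (y2 - y0) * (m1 - m0) / (m2 - m0)
    val = float(np.sum((y1 - pred) ** 2) / (n - 2))
    return float(np.sqrt(val)) if root else val


def _tsnoise_stack(ndvi: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Vectorized per-pixel TSNoise over a (T, H, W) stack with NaN gaps."""
    t = ndvi.shape[0]
    valid = np.isfinite(ndvi)
    n = valid.sum(axis=0)
    # stable-sort valid observations to the front of the time axis
    order = np.argsort(~valid, axis=0, kind="stable")
    ys = np.take_along_axis(ndvi, order, axis=0)
    mm = np.broadcast_to(months.astype(np.float64)[:, None, None],
                         ndvi.shape).copy()
    ms = np.take_along_axis(mm, order, axis=0)
    acc = np.zeros(ndvi.shape[1:], dtype=np.float64)
    for i in range(t - 2):
        use = n >= i + 3
        if not np.any(use):
            break
        y0, y1, y2 = ys[i], ys[i + 1], ys[i + 2]
        m0, m1, m2 = ms[i], ms[i + 1], ms[i + 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = y0 + (y2 - y0) * (m1 - m0) / (m2 - m0)
            d2 = (y1 - pred) ** 2
        acc[use] += d2[use]
    out = np.full(ndvi.shape[1:], np.nan)
    ok = n >= 3
    out[ok] = acc[ok] / (n[ok] - 2)
    return out


@dataclass
class NoiseMap:
    """Per-pixel TSNoise raster (NDVI^2 units) with the valid-month count."""

    values: np.ndarray
    n_valid: np.ndarray
    pixel_size: float

    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def density(self, bins: int = 50, value_range=None) -> pd.DataFrame:
        """Histogram summary of the defined noise values."""
        vals = self.values[np.isfinite(self.values)]
        counts, edges = np.histogram(vals, bins=bins, range=value_range)
        return pd.DataFrame({
            "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
        })


def noise_map(series: MonthlySeries) -> NoiseMap:
    """Per-pixel TSNoise over the valid months of a monthly series."""
    ndvi = series.ndvi(masked=True)
    values = _tsnoise_stack(ndvi, series.months)
    return NoiseMap(values, series.valid.sum(axis=0), series.pixel_size)
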