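"""Grid-cell summaries of classified maps and the fallow-vs-cropland curve.

A classified map is reduced to per-cell class fractions (exact pixel
counts; partial edge cells use their actual pixel count), from which the
share of active cropland, short-term fallow, total cropland and the
fallow fraction of total cropland are derived. The binned relationship
between fallow fraction and total-cropland fraction across cells
summarizes agricultural consolidation: consolidated production regions
tend to carry higher fallow shares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ACTIVE_CROPLAND, SHORT_FALLOW, ClassMap


def gridcell_fractions(class_map: ClassMap, cell_size_px: int) -> pd.DataFrame:
    """Per-cell class fractions of active cropland and short-term fallow.

    Columns: cell row/col index, pixel count, share_active, share_fallow,
    share_cropland (= active + fallow) and fallow_fraction (of total
    cropland; NaN where the cell has no cropland).
    """
    if cell_size_px < 1:
        raise ValueError("cell size must be at least one pixel")
    codes = class_map.codes
    h, w = codes.shape
    rows = []
    for r0 in range(0, h, cell_size_px):
        for c0 in range(0, w, cell_size_px):
            block = codes[r0:r0 + cell_size_px, c0:c0 + cell_size_px]
            n = block.size
            active = float(np.count_nonzero(block == ACTIVE_CROPLAND)) / n
            fallow = float(np.count_nonzero(block == SHORT_FALLOW)) / n
            total = active + fallow
            rows.append({
                "cell_row": r0 // cell_size_px,
                "cell_col": c0 // cell_size_px,
                "n_pixels": n,
                "share_active": active,
                "share_fallow": fallow,
                "share_cropland": total,
                "fallow_fraction": fallow / total if total > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def fallow_share_curve(summary: pd.DataFrame, bins=10) -> pd.DataFrame:
    """Binned medians of fallow fraction versus total-cropland fraction.

    Cells without cropland are excluded. ``bins`` is an integer count of
    equal-width bins over [0, max share] or an explicit edge sequence.
    Returns per-bin count, median and interquartile range.
    """
    df = summary[summary["share_cropland"] > 0].copy()
    if df.empty:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count",
                                     "median", "q25", "q75"])
    if np.isscalar(bins):
        edges = np.linspace(0.0, float(df["share_cropland"].max()),
                            int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.clip(np.digitize(df["share_cropland"], edges) - 1, 0,
                  len(edges) - 2)
    out = []
    for b in range(len(edges) - 1):
        vals = df.loc[idx == b, "fallow_fraction"].dropna()
        if vals.empty:
            continue
        out.append({
            "bin_left": edges[b], "bin_right": edges[b + 1],
            "count": len(vals), "median": float(vals.median()),
            "q25": float(vals.quantile(0.25)),
            "q75": float(vals.quantile(0.75)),
        })
    return pd.DataFrame(out)


def map_class_shares(class_map: ClassMap) -> dict[int, float]:
    """Pixel-count class shares of the full map (aggregation conserves
    these: cell-weighted means of the grid fractions reproduce them)."""
    return class_map.empirical_proportions()


def fallow_share_of_cropland(class_map: ClassMap) -> float:
    """Map-based fallow share of total cropland; NaN if no cropland."""
    shares = map_class_shares(class_map)
    active = shares.get(ACTIVE_CROPLAND, 0.0)
    fallow = shares.get(SHORT_FALLOW, 0.0)
    total = active + fallow
    return fallow / total if total > 0 else float("nan")
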