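"""Shared containers for the mapping pipeline.

All geometry is kept in pixel units with a nominal pixel size (meters)
recorded as metadata. Grids are row-major; ``x`` (east) increases with
column index, ``y`` (north) increases with row index, and coordinates
refer to pixel centers: pixel (0, 0) has center ``origin + pixel_size/2``
on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Nominal pixel size of the monthly mosaics, meters.
DEFAULT_PIXEL_SIZE = 4.77

# Seven-class catalog used throughout: codes are stable and ordered so the
# deterministic argmax tie-break ("lowest code wins") is well defined.
ACTIVE_CROPLAND = 1
SHORT_FALLOW = 2
HERBACEOUS = 3
OPEN_WOODLAND = 4
CLOSED_WOODLAND = 5
UNVEGETATED = 6
WATER = 7

CLASS_NAMES: dict[int, str] = {
    ACTIVE_CROPLAND: "active_cropland",
    SHORT_FALLOW: "short_fallow",
    HERBACEOUS: "herbaceous",
    OPEN_WOODLAND: "open_woodland",
    CLOSED_WOODLAND: "closed_woodland",
    UNVEGETATED: "unvegetated",
    WATER: "water",
}

ALL_CLASSES: tuple[int, ...] = tuple(CLASS_NAMES)

BAND_NAMES: tuple[str, ...] = ("green", "red", "nir", "extra")

#: Default 4-month season windows (month indices 0..11 of a season-year
#: starting in September): Sep-Dec, Jan-Apr, May-Aug.
SEASON_WINDOWS: tuple[tuple[int, ...], ...] = (
    (0, 1, 2, 3),
    (4, 5, 6, 7),
    (8, 9, 10, 11),
)


@dataclass
class ClassMap:
    """Single-band raster of class codes with generation-time proportions."""

    codes: np.ndarray  # (H, W) integer class codes
    pixel_size: float = DEFAULT_PIXEL_SIZE
    origin: tuple[float, float] = (0.0, 0.0)
    proportions: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("class map must be 2-D")
        if not self.proportions:
            self.proportions = self.empirical_proportions()

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def empirical_proportions(self) -> dict[int, float]:
        total = self.codes.size
        vals, counts = np.unique(self.codes, return_counts=True)
        return {int(v): float(c) / total for v, c in zip(vals, counts)}


@dataclass
class MonthlySeries:
    """Stack of monthly multiband rasters with validity masks.

    ``data`` has shape (n_months, n_bands, H, W); ``months`` holds integer
    month positions (used as the time axis of the noise statistic, so gaps
    are allowed); ``valid`` flags usable observations per month and pixel.
    """

    data: np.ndarray
    months: np.ndarray
    valid: np.ndarray
    band_names: tuple[str, ...] = BAND_NAMES
    pixel_size: float = DEFAULT_PIXEL_SIZE
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.months = np.asarray(self.months, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("series data must be (months, bands, H, W)")
        if self.months.shape[0] != self.data.shape[0]:
            raise ValueError("months length must match the time axis")
        if self.valid.shape != (self.data.shape[0],) + self.data.shape[2:]:
            raise ValueError("validity mask must be (months, H, W)")
        if np.any(np.diff(self.months) <= 0):
            raise ValueError("months must be strictly increasing")

    @property
    def n_months(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def band(self, name: str) -> np.ndarray:
        return self.data[:, self.band_names.index(name)]

    def ndvi(self, masked: bool = True) -> np.ndarray:
        """Per-month NDVI, NaN outside the validity mask when ``masked``."""
        red = self.band("red").astype(np.float64)
        nir = self.band("nir").astype(np.float64)
        denom = nir + red
        out = np.divide(nir - red, denom, out=np.zeros_like(denom),
                        where=np.abs(denom) > 1e-12)
        if masked:
            out = np.where(self.valid, out, np.nan)
        return out

    def copy(self) -> "MonthlySeries":
        return MonthlySeries(
            self.data.copy(), self.months.copy(), self.valid.copy(),
            self.band_names, self.pixel_size, self.origin,
        )


@dataclass
class DisplacementField:
    """Per-pixel (dx, dy) offsets, in pixels, mapping a target onto a
    reference geometry: the aligned image samples the target at
    ``(row + dy, col + dx)``."""

    dx: np.ndarray
    dy: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    max_offset_m: float = 100.0
    stiffness: float = 5.0

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=np.float64)
        self.dy = np.asarray(self.dy, dtype=np.float64)
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must share a grid")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)

    def clamp(self) -> "DisplacementField":
        """Clamp offset magnitudes to ``max_offset_m`` (in-place)."""
        cap = self.max_offset_m / self.pixel_size
        mag = self.magnitude
        over = mag > cap
        if np.any(over):
            scale = np.ones_like(mag)
            scale[over] = cap / mag[over]
            self.dx *= scale
            self.dy *= scale
        return self


@dataclass
class FeatureStack:
    """Named per-pixel feature layers on a single grid."""

    names: list[str]
    data: np.ndarray  # (n_layers, H, W)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per layer required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Feature matrix (n_points, n_layers) at the containing pixels
        (no interpolation)."""
        return self.data[:, np.asarray(rows), np.asarray(cols)].T

    def manifest(self) -> dict:
        return {
            "n_layers": len(self.names),
            "layers": list(self.names),
            "pixel_size": self.pixel_size,
            "origin": list(self.origin),
            "shape": list(self.shape),
        }


@dataclass
class LabeledSample:
    """Point sample: pixel location, class label and provenance."""

    row: int
    col: int
    x: float
    y: float
    class_code: int
    provenance: str = "random"  # random | augmented | validation
    split: str = "train"

    @staticmethod
    def to_frame(samples: Sequence["LabeledSample"]):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "row": s.row, "col": s.col, "x": s.x, "y": s.y,
                    "class_code": s.class_code, "provenance": s.provenance,
                    "split": s.split,
                }
                for s in samples
            ]
        )


def pixel_centers(shape: tuple[int, int], pixel_size: float,
                  origin: tuple[float, float] = (0.0, 0.0)):
    """(y, x) coordinate rasters of pixel centers."""
    rows = np.arange(shape[0])[:, None] + 0.5
    cols = np.arange(shape[1])[None, :] + 0.5
    y = origin[1] + np.broadcast_to(rows * pixel_size, shape).copy()
    x = origin[0] + np.broadcast_to(cols * pixel_size, shape).copy()
    return y, x
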