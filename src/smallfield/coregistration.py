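"""Multi-temporal coregistration by multi-scale block cross-correlation.

Each monthly mosaic is matched against a seasonal near-infrared reference
composite (a per-pixel median over a 4-month window, which damps the
seasonality that would otherwise masquerade as displacement). Matching is
coarse-to-fine: at every pyramid level the residual offset of each block
is estimated by normalized cross-correlation with sub-pixel refinement,
uninformative blocks (low correlation peak or no texture) inherit the
smoothed neighborhood estimate, and the block field is regularized by a
Gaussian smoother whose strength grows with the ``stiffness`` setting.
Offsets are clamped to a maximum (default 100 m) and all spectral bands
are warped through the single NIR-derived field. Large rasters can be
processed in buffered tiles to bound memory without seam artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.transform import resize

from .core import (DEFAULT_PIXEL_SIZE, SEASON_WINDOWS, DisplacementField,
                   MonthlySeries)


@dataclass
class CoregConfig:
    max_offset_m: float = 100.0
    stiffness: float = 5.0
    levels: int = 3
    block_size: int = 64
    min_correlation: float = 0.3
    pixel_size: float = DEFAULT_PIXEL_SIZE
    tile_size: int | None = None   # pixels; None = untiled
    tile_buffer: int | None = None  # pixels; defaults to ceil(max offset)
    season_windows: tuple = SEASON_WINDOWS

    def __post_init__(self) -> None:
        if self.max_offset_m <= 0:
            raise ValueError("max_offset_m must be positive")
        if self.levels < 1:
            raise ValueError("need at least one pyramid level")
        if self.tile_buffer is None:
            self.tile_buffer = int(np.ceil(self.max_offset_m / self.pixel_size))
        if self.tile_size is not None and self.tile_buffer < self.max_offset_px:
            raise ValueError("tile buffer must cover the maximum offset")

    @property
    def max_offset_px(self) -> float:
        return self.max_offset_m / self.pixel_size

    def stiffness_sigma(self) -> float:
        """Gaussian sigma (in blocks) applied to the block displacement
        grid; scaled so the default stiffness of 5 strongly suppresses
        block-to-block jitter while staying monotone in stiffness."""
        return 0.4 * max(self.stiffness, 0.0)


@dataclass
class SeasonalReference:
    """Per-season NIR composite with a valid-observation count layer."""

    composite: np.ndarray   # (H, W), NaN where undefined
    count: np.ndarray       # (H, W) valid observations contributing
    season: int
    months: tuple
    pixel_size: float = DEFAULT_PIXEL_SIZE

    @property
    def defined(self) -> np.ndarray:
        return self.count > 0


def build_seasonal_reference(series: MonthlySeries,
                             season_windows=SEASON_WINDOWS
                             ) -> list[SeasonalReference]:
    """Median NIR composite per season window over valid observations."""
    idx = sorted(i for w in season_windows for i in w)
    if idx != list(range(series.n_months)):
        raise ValueError("season windows must partition the months")
    nir = series.band("nir").astype(np.float64)
    nir = np.where(series.valid, nir, np.nan)
    refs = []
    for s, window in enumerate(season_windows):
        block = nir[list(window)]
        count = np.isfinite(block).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            comp = np.nanmedian(block, axis=0)
        refs.append(SeasonalReference(comp, count, season=s,
                                      months=tuple(window),
                                      pixel_size=series.pixel_size))
    return refs


def season_of_month(month_index: int, season_windows=SEASON_WINDOWS) -> int:
    for s, window in enumerate(season_windows):
        if month_index in window:
            return s
    raise ValueError(f"month index {month_index} not covered by any season")


def _subpixel_peak(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Quadratic (parabolic) refinement of an integer correlation peak."""
    py, px = peak
    dy = dx = 0.0
    if 0 < py < corr.shape[0] - 1:
        c0, c1, c2 = corr[py - 1, px], corr[py, px], corr[py + 1, px]
        denom = c0 - 2 * c1 + c2
        if abs(denom) > 1e-12:
            dy = float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
    if 0 < px < corr.shape[1] - 1:
        c0, c1, c2 = corr[py, px - 1], corr[py, px], corr[py, px + 1]
        denom = c0 - 2 * c1 + c2
        if abs(denom) > 1e-12:
            dx = float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
    return dy, dx


def _block_offsets(reference, target, block, radius, min_corr):
    """Estimate per-block offsets of ``target`` relative to ``reference``.

    Returns block-grid arrays (dy, dx, confidence). Offsets follow the
    warp convention: sampling the target at (p + d) aligns it with the
    reference at p.
    """
    h, w = reference.shape
    nby = max(1, int(np.ceil(h / block)))
    nbx = max(1, int(np.ceil(w / block)))
    dy = np.zeros((nby, nbx))
    dx = np.zeros((nby, nbx))
    conf = np.zeros((nby, nbx), dtype=bool)
    ref_pad = np.pad(reference, radius, mode="edge")
    for by in range(nby):
        r0 = by * block
        r1 = min(r0 + block, h)
        for bx in range(nbx):
            c0 = bx * block
            c1 = min(c0 + block, w)
            tmpl = target[r0:r1, c0:c1]
            if tmpl.size < 16 or not np.all(np.isfinite(tmpl)):
                continue
            if tmpl.std() < 1e-8:
                continue
            window = ref_pad[r0:r1 + 2 * radius, c0:c1 + 2 * radius]
            if not np.all(np.isfinite(window)) or window.std() < 1e-8:
                continue
            corr = match_template(window, tmpl)
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            peak_val = corr[peak]
            if peak_val < min_corr:
                continue
            sy, sx = _subpixel_peak(corr, peak)
            # template found at offset o in the reference => warp by -o
            dy[by, bx] = -(peak[0] - radius + sy)
            dx[by, bx] = -(peak[1] - radius + sx)
            conf[by, bx] = True
    # spurious correlation peaks (repetitive texture, clouds) can land far
    # from the consensus; reject blocks deviating strongly from the median
    # confident offset, since the true field is smooth by assumption
    if conf.sum() >= 3:
        for arr in (dy, dx):
            med = np.median(arr[conf])
            mad = np.median(np.abs(arr[conf] - med))
            tol = max(3.0 * 1.4826 * mad, 2.0)
            conf &= np.abs(arr - med) <= tol
    return dy, dx, conf


def _regularize(dy, dx, conf, sigma):
    """Normalized-convolution smoothing: confident blocks drive the field,
    uninformative ones inherit the smoothed neighborhood estimate."""
    if not np.any(conf):
        return np.zeros_like(dy), np.zeros_like(dx)
    wgt = conf.astype(np.float64)
    if sigma <= 0:
        # still need to fill unconfident blocks: use the confident mean
        fy = np.where(conf, dy, dy[conf].mean())
        fx = np.where(conf, dx, dx[conf].mean())
        return fy, fx
    sw = ndimage.gaussian_filter(wgt, sigma, mode="nearest")
    fy = ndimage.gaussian_filter(dy * wgt, sigma, mode="nearest")
    fx = ndimage.gaussian_filter(dx * wgt, sigma, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        fy = np.where(sw > 1e-12, fy / sw, 0.0)
        fx = np.where(sw > 1e-12, fx / sw, 0.0)
    return fy, fx


def _warp2d(img, dy, dx, order=1):
    rows, cols = np.meshgrid(np.arange(img.shape[0], dtype=np.float64),
                             np.arange(img.shape[1], dtype=np.float64),
                             indexing="ij")
    return ndimage.map_coordinates(img, [rows + dy, cols + dx], order=order,
                                   mode="nearest")


def _downscale(img, factor):
    if factor == 1:
        return img
    h, w = img.shape
    return resize(img, (max(8, h // factor), max(8, w // factor)), order=1,
                  mode="edge", anti_aliasing=True, preserve_range=True)


def estimate_displacement(target: np.ndarray, reference: SeasonalReference,
                          cfg: CoregConfig | None = None) -> DisplacementField:
    """Estimate the displacement field aligning ``target`` to the reference.

    Coarse-to-fine block matching: at the coarsest level the search radius
    covers the configured maximum offset; finer levels refine residuals
    within a small window. The returned field satisfies the clamp contract
    (no offset exceeds ``max_offset_m``).
    """
    cfg = cfg or CoregConfig()
    ref = np.asarray(reference.composite, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    if ref.shape != tgt.shape:
        raise ValueError("target and reference grids differ")
    finite = np.isfinite(ref) & np.isfinite(tgt)
    if finite.mean() <= 0.25:
        raise ValueError("defined-pixel overlap below 25%")
    fill = np.nanmean(ref[np.isfinite(ref)]) if np.any(np.isfinite(ref)) else 0.0
    ref = np.where(np.isfinite(ref), ref, fill)
    tgt = np.where(np.isfinite(tgt), tgt, fill)

    h, w = ref.shape
    if tgt.std() < 1e-8:
        warnings.warn("textureless target: returning zero displacement",
                      stacklevel=2)
        zero = np.zeros((h, w))
        return DisplacementField(zero.copy(), zero, cfg.pixel_size,
                                 cfg.max_offset_m, cfg.stiffness)

    cap = cfg.max_offset_px
    dy_full = np.zeros((h, w))
    dx_full = np.zeros((h, w))
    # cap pyramid depth so the coarsest level still holds a few blocks;
    # small scenes otherwise produce junk estimates at the coarse levels
    levels = cfg.levels
    while levels > 1 and min(h, w) // 2 ** (levels - 1) < 2 * max(
            16, cfg.block_size // 2 ** (levels - 1)):
        levels -= 1
    any_conf = False
    for level in range(levels - 1, -1, -1):
        scale = 2 ** level
        tgt_w = _warp2d(tgt, dy_full, dx_full) if any_conf else tgt
        ref_l = _downscale(ref, scale)
        tgt_l = _downscale(tgt_w, scale)
        block_l = max(16, cfg.block_size // scale)
        if level == levels - 1:
            radius = int(np.ceil(cap / scale)) + 2
        else:
            radius = 6  # residual search after the coarse estimate
        radius = min(radius, max(ref_l.shape) // 2)
        bdy, bdx, conf = _block_offsets(ref_l, tgt_l, block_l, radius,
                                        cfg.min_correlation)
        if not np.any(conf):
            continue
        any_conf = True
        fy, fx = _regularize(bdy, bdx, conf, cfg.stiffness_sigma())
        dy_up = resize(fy * scale, (h, w), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
        dx_up = resize(fx * scale, (h, w), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
        dy_full += dy_up
        dx_full += dx_up
        mag = np.hypot(dy_full, dx_full)
        over = mag > cap
        if np.any(over):
            s = np.ones_like(mag)
            s[over] = cap / mag[over]
            dy_full *= s
            dx_full *= s
    if not any_conf:
        warnings.warn("no confident correlation blocks: returning zero "
                      "displacement", stacklevel=2)
    out = DisplacementField(dx_full, dy_full, cfg.pixel_size,
                            cfg.max_offset_m, cfg.stiffness)
    return out.clamp()


def apply_displacement(series: MonthlySeries, fields) -> MonthlySeries:
    """Warp all bands of a monthly series through displacement field(s).

    ``fields`` is one field applied to every month or a per-month list.
    Spectral bands are interpolated bilinearly; the validity mask is warped
    with nearest-neighbor so flags stay boolean. A zero field leaves the
    month untouched bit-for-bit.
    """
    if isinstance(fields, DisplacementField):
        fields = [fields] * series.n_months
    if len(fields) != series.n_months:
        raise ValueError("need one displacement field per month")
    out = series.copy()
    h, w = series.shape
    rows, cols = np.meshgrid(np.arange(h, dtype=np.float64),
                             np.arange(w, dtype=np.float64), indexing="ij")
    for m, fld in enumerate(fields):
        if fld.dx.shape != (h, w):
            raise ValueError("displacement grid does not match the series")
        if not np.any(fld.dx) and not np.any(fld.dy):
            continue
        coords = [rows + fld.dy, cols + fld.dx]
        for b in range(series.data.shape[1]):
            out.data[m, b] = ndimage.map_coordinates(
                series.data[m, b].astype(np.float64), coords, order=1,
                mode="nearest")
        out.valid[m] = ndimage.map_coordinates(
            series.valid[m].astype(np.uint8), coords, order=0,
            mode="nearest").astype(bool)
    return out


def _tiles(h, w, tile, buf):
    for r0 in range(0, h, tile):
        for c0 in range(0, w, tile):
            r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
            br0, bc0 = max(0, r0 - buf), max(0, c0 - buf)
            br1, bc1 = min(h, r1 + buf), min(w, c1 + buf)
            yield (r0, r1, c0, c1), (br0, br1, bc0, bc1)


def coregister_series(series: MonthlySeries, cfg: CoregConfig | None = None,
                      references: list[SeasonalReference] | None = None
                      ) -> tuple[MonthlySeries, list[DisplacementField]]:
    """Coregister every month against the reference of its season.

    References default to seasonal NIR median composites of the input
    series itself. When ``cfg.tile_size`` is set, displacement estimation
    runs per buffered tile and only tile cores are written back, so the
    buffer (>= the maximum offset in pixels) prevents edge seams.
    """
    cfg = cfg or CoregConfig(pixel_size=series.pixel_size)
    refs = references or build_seasonal_reference(series, cfg.season_windows)
    nir = series.band("nir").astype(np.float64)
    nir = np.where(series.valid, nir, np.nan)
    h, w = series.shape
    fields: list[DisplacementField] = []
    for m in range(series.n_months):
        ref = refs[season_of_month(m, cfg.season_windows)]
        if cfg.tile_size is None:
            fld = estimate_displacement(nir[m], ref, cfg)
        else:
            dy = np.zeros((h, w))
            dx = np.zeros((h, w))
            for core, buffered in _tiles(h, w, cfg.tile_size, cfg.tile_buffer):
                r0, r1, c0, c1 = core
                br0, br1, bc0, bc1 = buffered
                sub_ref = SeasonalReference(
                    ref.composite[br0:br1, bc0:bc1],
                    ref.count[br0:br1, bc0:bc1],
                    ref.season, ref.months, ref.pixel_size)
                sub = estimate_displacement(nir[m, br0:br1, bc0:bc1],
                                            sub_ref, cfg)
                dy[r0:r1, c0:c1] = sub.dy[r0 - br0:r1 - br0, c0 - bc0:c1 - bc0]
                dx[r0:r1, c0:c1] = sub.dx[r0 - br0:r1 - br0, c0 - bc0:c1 - bc0]
            fld = DisplacementField(dx, dy, cfg.pixel_size, cfg.max_offset_m,
                                    cfg.stiffness).clamp()
        fields.append(fld)
    corrected = apply_displacement(series, fields)
    return corrected, fields
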