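"""Seeded synthetic scenes for end-to-end testing of the mapping pipeline.

The generator emulates the structural traits of fragmented smallholder
landscapes: small contiguous fields (most below 1 ha), class-specific
seasonal NDVI phenology over a season-year starting in September, smooth
per-month geometric displacement of the mosaics, and cloud contamination
recorded in validity masks. Every stage is deterministic under a seed, and
the ground truth (class map, displacement, clouds, terrain) is retained so
downstream estimates can be scored against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import (
    ACTIVE_CROPLAND, ALL_CLASSES, BAND_NAMES, CLASS_NAMES, CLOSED_WOODLAND,
    DEFAULT_PIXEL_SIZE, HERBACEOUS, OPEN_WOODLAND, SHORT_FALLOW, UNVEGETATED,
    WATER, ClassMap, LabeledSample, MonthlySeries,
)

#: Class mix of the mapped study region (error-adjusted shares): active
#: cropland 16.2%, short-term fallow 6.6%, herbaceous 11.2%, open woodland
#: 39.1%, closed woodland 24.0%, unvegetated 2.1%, water 0.7%.
DEFAULT_CLASS_MIX: dict[int, float] = {
    ACTIVE_CROPLAND: 0.162,
    SHORT_FALLOW: 0.066,
    HERBACEOUS: 0.112,
    OPEN_WOODLAND: 0.391,
    CLOSED_WOODLAND: 0.240,
    UNVEGETATED: 0.021,
    WATER: 0.008,
}

# Monthly mean NDVI trajectories (Sep..Aug). The region has a single wet
# season roughly Nov-Apr: cropland shows a pronounced green-up/harvest
# cycle from a bare, recently-managed start; fallows green up with the
# rains but lack the management signal; woodlands stay greener with damped
# seasonality. Values are free parameters of the simulator (the field
# provides no canonical trajectories) chosen to keep the pairwise class
# contrast realistic rather than trivially separable.
DEFAULT_PHENOLOGY: dict[int, tuple[float, ...]] = {
    ACTIVE_CROPLAND: (0.22, 0.20, 0.30, 0.55, 0.75, 0.82, 0.78, 0.60,
                      0.40, 0.28, 0.24, 0.22),
    SHORT_FALLOW:    (0.30, 0.28, 0.34, 0.45, 0.58, 0.65, 0.64, 0.58,
                      0.48, 0.40, 0.35, 0.32),
    HERBACEOUS:      (0.28, 0.26, 0.34, 0.52, 0.68, 0.74, 0.72, 0.62,
                      0.46, 0.36, 0.31, 0.29),
    OPEN_WOODLAND:   (0.45, 0.43, 0.48, 0.58, 0.68, 0.72, 0.71, 0.66,
                      0.58, 0.52, 0.48, 0.46),
    CLOSED_WOODLAND: (0.72, 0.70, 0.72, 0.76, 0.80, 0.82, 0.82, 0.80,
                      0.78, 0.76, 0.74, 0.73),
    UNVEGETATED:     (0.10, 0.10, 0.10, 0.12, 0.14, 0.14, 0.13, 0.12,
                      0.11, 0.10, 0.10, 0.10),
    WATER:           (-0.30, -0.30, -0.28, -0.25, -0.22, -0.22, -0.24,
                      -0.26, -0.28, -0.30, -0.30, -0.30),
}

#: Total red+NIR reflectance per class, used to map NDVI to band values.
DEFAULT_BRIGHTNESS: dict[int, float] = {
    ACTIVE_CROPLAND: 0.42,
    SHORT_FALLOW: 0.40,
    HERBACEOUS: 0.40,
    OPEN_WOODLAND: 0.36,
    CLOSED_WOODLAND: 0.32,
    UNVEGETATED: 0.55,
    WATER: 0.10,
}


@dataclass
class PhenologyLibrary:
    """Per-class 12-month NDVI trajectories plus a band mapping.

    Bands derive from NDVI ``v`` and a class brightness ``L`` (= red+NIR)
    as ``red = L(1-v)/2`` and ``nir = L(1+v)/2`` so that the NDVI of a
    rendered pixel reproduces the trajectory exactly in the noiseless case.
    """

    ndvi: dict[int, np.ndarray] = field(default_factory=dict)
    brightness: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if not self.ndvi:
            self.ndvi = {c: np.asarray(t, dtype=np.float64)
                         for c, t in DEFAULT_PHENOLOGY.items()}
        else:
            self.ndvi = {c: np.asarray(t, dtype=np.float64)
                         for c, t in self.ndvi.items()}
        if not self.brightness:
            self.brightness = dict(DEFAULT_BRIGHTNESS)
        for c, traj in self.ndvi.items():
            if traj.shape != (12,):
                raise ValueError(f"trajectory for class {c} must have 12 months")
            if np.any(np.abs(traj) > 1):
                raise ValueError(f"NDVI trajectory for class {c} leaves [-1, 1]")

    def bands(self, class_code: int) -> np.ndarray:
        """(12, 4) band trajectory (green, red, nir, extra) for a class."""
        v = self.ndvi[class_code]
        L = self.brightness[class_code]
        red = L * (1.0 - v) / 2.0
        nir = L * (1.0 + v) / 2.0
        green = 0.9 * red + 0.02
        extra = 0.5 * (green + red)
        return np.stack([green, red, nir, extra], axis=1)


@dataclass
class SceneTruth:
    """Complete ground truth of a simulated scene."""

    class_map: ClassMap
    displacement: np.ndarray  # (12, 2, H, W): (dy, dx) per month, pixels
    clouds: np.ndarray        # (12, H, W) boolean, True = contaminated
    dem: np.ndarray           # (H, W) elevation, meters
    max_displacement_px: float = 0.0
    cloud_fraction: float = 0.0


def _smooth_field(shape, rng, sigma):
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, sigma, mode="reflect")
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def generate_class_map(extent, class_mix=None, mean_field_area_m2=5000.0,
                       pixel_size=DEFAULT_PIXEL_SIZE, seed=0,
                       boundary_roughness=0.35) -> ClassMap:
    """Generate a patchy class map by seeded region growth on a jittered grid.

    Seed points are laid on a jittered grid whose cell area matches the
    requested mean field area (default 0.5 ha, reflecting landscapes where
    most fields are below 1 ha); each seed is assigned a class by exact
    largest-remainder allocation of the requested mix, and pixels take the
    class of their nearest seed through a smoothly warped coordinate space,
    which yields contiguous, irregular patches.

    Parameters
    ----------
    extent : int or (int, int)
        Grid size in pixels; at least 64 x 64.
    class_mix : dict, optional
        Class code -> requested proportion; must sum to 1. Defaults to the
        study-region mix.
    """
    if np.isscalar(extent):
        extent = (int(extent), int(extent))
    h, w = int(extent[0]), int(extent[1])
    if h < 64 or w < 64:
        raise ValueError(f"extent {h}x{w} too small: need at least 64x64 pixels")
    mix = dict(DEFAULT_CLASS_MIX) if class_mix is None else dict(class_mix)
    if not mix:
        raise ValueError("class mix is empty")
    unknown = set(mix) - set(ALL_CLASSES)
    if unknown:
        raise ValueError(f"unknown class codes in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"class proportions must sum to 1 (got {total:g})")

    rng = np.random.default_rng(seed)
    cell_px = max(2.0, np.sqrt(mean_field_area_m2) / pixel_size)
    ny = max(2, int(round(h / cell_px)))
    nx = max(2, int(round(w / cell_px)))
    gy, gx = np.meshgrid((np.arange(ny) + 0.5) * h / ny,
                         (np.arange(nx) + 0.5) * w / nx, indexing="ij")
    jitter = 0.45
    gy = gy + rng.uniform(-jitter, jitter, gy.shape) * h / ny
    gx = gx + rng.uniform(-jitter, jitter, gx.shape) * w / nx
    seeds = np.column_stack([gy.ravel(), gx.ravel()])

    # exact largest-remainder class allocation over seeds
    codes = sorted(mix)
    n_seeds = len(seeds)
    quotas = np.array([mix[c] * n_seeds for c in codes])
    counts = np.floor(quotas).astype(int)
    rem = n_seeds - counts.sum()
    order = np.argsort(-(quotas - np.floor(quotas)), kind="stable")
    counts[order[:rem]] += 1
    seed_classes = np.repeat(codes, counts)
    rng.shuffle(seed_classes)

    rows, cols = np.meshgrid(np.arange(h, dtype=np.float64),
                             np.arange(w, dtype=np.float64), indexing="ij")
    if boundary_roughness > 0 and len(codes) > 1:
        amp = boundary_roughness * cell_px
        rows = rows + amp * _smooth_field((h, w), rng, cell_px / 2)
        cols = cols + amp * _smooth_field((h, w), rng, cell_px / 2)
    _, idx = cKDTree(seeds).query(np.column_stack([rows.ravel(), cols.ravel()]))
    grid = seed_classes[idx].reshape(h, w).astype(np.uint8)
    return ClassMap(grid, pixel_size=pixel_size)


def generate_displacements(shape, n_months=12, max_shift_px=3.0, seed=0,
                           constant_shifts=None) -> np.ndarray:
    """Per-month smooth displacement fields, (n_months, 2, H, W) as (dy, dx).

    Fields are low-frequency Gaussian random fields scaled to a random
    per-month magnitude up to ``max_shift_px``; ``constant_shifts`` may give
    an explicit (dy, dx) pair per month instead (None entries keep the
    smooth field).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    out = np.zeros((n_months, 2, h, w))
    sigma = max(h, w) / 4
    for m in range(n_months):
        const = None if constant_shifts is None else constant_shifts[m]
        if const is not None:
            out[m, 0] = const[0]
            out[m, 1] = const[1]
        else:
            amp = rng.uniform(0.0, max_shift_px)
            out[m, 0] = amp * _smooth_field((h, w), rng, sigma)
            out[m, 1] = amp * _smooth_field((h, w), rng, sigma)
    return out


def generate_clouds(shape, n_months=12, cloud_fraction=0.1, seed=0,
                    mean_radius_px=None) -> np.ndarray:
    """Monthly cloud masks as unions of random elliptical blobs.

    Blobs are added while the masked fraction stays below the target; a
    blob that would move the fraction further from the target than it
    already is gets rejected and the month is closed, so the realized
    fraction lands within roughly one blob area of the request. The
    default blob radius scales with the target so that granularity stays
    a small fraction of it.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if mean_radius_px is None:
        mean_radius_px = max(3.0, np.sqrt(cloud_fraction * h * w
                                          / (10 * np.pi)))
    masks = np.zeros((n_months, h, w), dtype=bool)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for m in range(n_months):
        target = cloud_fraction * h * w
        guard = 0
        while masks[m].sum() < target and guard < 2000:
            guard += 1
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            a = rng.uniform(0.6, 1.5) * mean_radius_px
            b = rng.uniform(0.6, 1.5) * mean_radius_px
            th = rng.uniform(0, np.pi)
            dy, dx = yy - cy, xx - cx
            u = dy * np.cos(th) + dx * np.sin(th)
            v = -dy * np.sin(th) + dx * np.cos(th)
            blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            grown = masks[m] | blob
            if abs(grown.sum() - target) > abs(masks[m].sum() - target):
                break
            masks[m] = grown
    return masks


def generate_dem(shape, relief_m=300.0, seed=0) -> np.ndarray:
    """Smooth synthetic elevation: a regional ramp plus low-frequency hills."""
    rng = np.random.default_rng(seed)
    h, w = shape
    ramp = np.linspace(0, 1, w)[None, :] * np.ones((h, 1))
    hills = _smooth_field(shape, rng, max(h, w) / 6)
    return 200.0 + relief_m * (0.6 * ramp + 0.4 * hills)


def make_scene(extent=128, class_mix=None, mean_field_area_m2=5000.0,
               max_shift_px=3.0, cloud_fraction=0.1,
               pixel_size=DEFAULT_PIXEL_SIZE, seed=0,
               constant_shifts=None) -> SceneTruth:
    """Convenience constructor assembling a full :class:`SceneTruth`."""
    rng = np.random.default_rng(seed)
    s_map, s_disp, s_cloud, s_dem = rng.integers(0, 2**31 - 1, 4)
    cmap = generate_class_map(extent, class_mix=class_mix,
                              mean_field_area_m2=mean_field_area_m2,
                              pixel_size=pixel_size, seed=int(s_map))
    shape = cmap.shape
    disp = generate_displacements(shape, max_shift_px=max_shift_px,
                                  seed=int(s_disp),
                                  constant_shifts=constant_shifts)
    clouds = generate_clouds(shape, cloud_fraction=cloud_fraction,
                             seed=int(s_cloud))
    dem = generate_dem(shape, seed=int(s_dem))
    return SceneTruth(cmap, disp, clouds, dem,
                      max_displacement_px=float(np.hypot(disp[:, 0], disp[:, 1]).max()),
                      cloud_fraction=cloud_fraction)


def render_monthly_series(truth: SceneTruth, phen: PhenologyLibrary | None = None,
                          noise_sd: float | None = None, seed: int = 0,
                          texture_sd: float = 0.06) -> MonthlySeries:
    """Render the 12-month 4-band series implied by a scene truth.

    Each month's clean image combines the class phenology with a static
    per-pixel NDVI texture field (``texture_sd``), emulating the strong
    within-field heterogeneity of unmechanized smallholder landscapes;
    the texture belongs to the land surface and is warped along with it by
    the month's true displacement (so coregistration against an unwarped
    reference should recover the true field). White per-month NDVI noise
    (``noise_sd``) is added afterwards. Cloud-contaminated pixels are
    flagged invalid in the validity layer; their reflectance is left
    untouched, matching a compositing workflow that consumes masks rather
    than inspecting pixels.
    """
    phen = phen or PhenologyLibrary()
    sd = phen.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    codes = truth.class_map.codes
    h, w = codes.shape
    present = np.unique(codes)
    missing = [int(c) for c in present if int(c) not in phen.ndvi]
    if missing:
        names = ", ".join(CLASS_NAMES.get(c, str(c)) for c in missing)
        raise ValueError(f"phenology library missing classes: {names}")

    ndvi_lut = np.zeros((max(present) + 1, 12))
    bright_lut = np.zeros(max(present) + 1)
    for c in present:
        ndvi_lut[c] = phen.ndvi[int(c)]
        bright_lut[c] = phen.brightness[int(c)]

    texture = np.zeros((h, w))
    if texture_sd > 0:
        texture = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, (h, w)), 1.0, mode="reflect")
        texture *= texture_sd / max(texture.std(), 1e-12)

    brightness = bright_lut[codes]
    rows, cols = np.meshgrid(np.arange(h, dtype=np.float64),
                             np.arange(w, dtype=np.float64), indexing="ij")
    data = np.zeros((12, 4, h, w), dtype=np.float32)
    for m in range(12):
        v = np.clip(ndvi_lut[codes, m] + texture, -1.0, 1.0)
        red = brightness * (1.0 - v) / 2.0
        nir = brightness * (1.0 + v) / 2.0
        green = 0.9 * red + 0.02
        extra = 0.5 * (green + red)
        clean = np.stack([green, red, nir, extra])
        dy, dx = truth.displacement[m]
        if np.any(dy) or np.any(dx):
            coords = [rows - dy, cols - dx]
            warped = np.stack([
                ndimage.map_coordinates(clean[b], coords, order=1,
                                        mode="nearest")
                for b in range(4)
            ])
        else:
            warped = clean
        if sd > 0:
            # perturb NDVI and re-derive red/NIR so NDVI noise is exact
            green, red, nir, extra = warped
            tot = red + nir
            v = np.divide(nir - red, tot, out=np.zeros_like(tot),
                          where=np.abs(tot) > 1e-12)
            v = np.clip(v + rng.normal(0.0, sd, v.shape), -1.0, 1.0)
            red = tot * (1.0 - v) / 2.0
            nir = tot * (1.0 + v) / 2.0
            warped = np.stack([green, red, nir, extra])
        data[m] = warped
    valid = ~truth.clouds
    return MonthlySeries(data, np.arange(1, 13), valid,
                         band_names=BAND_NAMES,
                         pixel_size=truth.class_map.pixel_size)


def sample_reference_points(truth: SceneTruth, n_per_class: int,
                            min_dist_m: float = 222.0, seed: int = 0,
                            provenance: str = "random",
                            split: str = "train") -> list[LabeledSample]:
    """Random labeled points from the truth map with a global minimum
    pairwise distance.

    Candidates are visited in seeded random order per class and accepted
    greedily when at least ``min_dist_m`` from every previously accepted
    point (across classes). Classes too rare to satisfy both the count and
    the spacing yield a partial sample with a warning.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    cmap = truth.class_map
    px = cmap.pixel_size
    min_dist_px = min_dist_m / px
    accepted: list[LabeledSample] = []
    acc_rc: list[tuple[float, float]] = []
    shortfall = 0
    for code in sorted(np.unique(cmap.codes)):
        rs, cs = np.nonzero(cmap.codes == code)
        order = rng.permutation(len(rs))
        taken = 0
        for i in order:
            if taken >= n_per_class:
                break
            r, c = float(rs[i]), float(cs[i])
            if acc_rc:
                arr = np.asarray(acc_rc)
                if np.min(np.hypot(arr[:, 0] - r, arr[:, 1] - c)) < min_dist_px:
                    continue
            acc_rc.append((r, c))
            accepted.append(LabeledSample(
                row=int(r), col=int(c),
                x=cmap.origin[0] + (c + 0.5) * px,
                y=cmap.origin[1] + (r + 0.5) * px,
                class_code=int(code), provenance=provenance, split=split,
            ))
            taken += 1
        if taken < n_per_class:
            shortfall += n_per_class - taken
    if shortfall:
        warnings.warn(
            f"minimum-distance constraint left {shortfall} samples short of "
            f"{n_per_class} per class", stacklevel=2)
    return accepted
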