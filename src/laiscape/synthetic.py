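"""Synthetic agro-landscape generator.

Emulates the statistical structure of an intensively used arable loess
landscape: a mosaic of rectangular uniform-crop fields (log-normal field
areas, mean ~2 ha), crop-specific seasonal LAI curves, variance dominated by
inter-field differences with smaller intra-field pixel noise, an optional
kilometre-scale background field with exponential covariance, and a two-band
(NIR, Red) reflectance sensor model driven by NDVI.  Reference patches of
broadleaf forest (permanently vegetated) and bare ground (permanently
unvegetated) are included so that per-date NDVI endmembers can be estimated
from the scene itself.

All randomness derives from ``SceneConfig.seed``; identical configurations
produce bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.fft import fft2, ifft2, next_fast_len

from .raster import NODATA_CLASS, Raster

# land-use codes: crops are 1..n_crops in config order
OTHER_ARABLE_CODE = 9
FOREST_CODE = 10
BARE_CODE = 11

__all__ = [
    "CropCurve",
    "SceneConfig",
    "SceneTruth",
    "generate_mosaic",
    "simulate_lai",
    "forward_ndvi",
    "gaussian_random_field",
    "true_field_map",
    "FOREST_CODE",
    "BARE_CODE",
    "OTHER_ARABLE_CODE",
]


def true_field_map(truth: "SceneTruth"):
    """FieldMap over the generator's true field labels (no segmentation).

    Unlike segmentation of the land-use raster, adjacent fields of the same
    crop stay distinct here; use this when the analysis should see the true
    parcel structure.
    """
    import pandas as pd

    from .fields import FieldMap

    labels = truth.field_labels.data
    res2 = truth.field_labels.resolution ** 2
    ids = np.array(sorted(truth.field_crop))
    counts = np.bincount(labels.ravel(), minlength=ids.max() + 1)
    rr, cc = np.indices(labels.shape)
    r_sum = np.bincount(labels.ravel(), weights=rr.ravel(), minlength=ids.max() + 1)
    c_sum = np.bincount(labels.ravel(), weights=cc.ravel(), minlength=ids.max() + 1)
    with np.errstate(invalid="ignore"):
        records = pd.DataFrame(
            {
                "id": ids,
                "code": [truth.field_crop[i] for i in ids],
                "pixels": counts[ids],
                "area_m2": counts[ids] * res2,
                "row": r_sum[ids] / counts[ids],
                "col": c_sum[ids] / counts[ids],
            }
        )
    return FieldMap(labels=truth.field_labels, records=records)


@dataclass(frozen=True)
class CropCurve:
    """Piecewise seasonal LAI curve for one crop.

    Logistic rise from ``emergence_day`` to ``peak_day`` reaching
    ``max_lai``, then a linear senescent decline to zero at
    ``senescence_end_day``.  Days are day-of-year.
    """

    emergence_day: float
    peak_day: float
    max_lai: float
    senescence_end_day: float

    def __post_init__(self) -> None:
        if not (self.emergence_day < self.peak_day < self.senescence_end_day):
            raise ValueError(
                "crop curve requires emergence < peak < senescence end, got "
                f"{self.emergence_day}, {self.peak_day}, {self.senescence_end_day}"
            )
        if self.max_lai < 0:
            raise ValueError("max LAI must be non-negative")

    def __call__(self, day: float) -> float:
        if day <= self.emergence_day:
            return 0.0
        if day <= self.peak_day:
            # logistic centred mid-way, steepness so the curve is ~0/~max at the ends
            mid = 0.5 * (self.emergence_day + self.peak_day)
            scale = (self.peak_day - self.emergence_day) / 10.0
            raw = 1.0 / (1.0 + np.exp(-(day - mid) / scale))
            lo = 1.0 / (1.0 + np.exp((mid - self.emergence_day) / scale))
            hi = 1.0 / (1.0 + np.exp((mid - self.peak_day) / scale))
            return self.max_lai * (raw - lo) / (hi - lo)
        if day < self.senescence_end_day:
            frac = (self.senescence_end_day - day) / (
                self.senescence_end_day - self.peak_day
            )
            return self.max_lai * frac
        return 0.0


#: Default seasonal curves for the three dominant crops of a temperate loess
#: plain: winter wheat grows from early March, sugar beet from mid-April,
#: maize from mid-May.
DEFAULT_CROP_CURVES: dict[str, CropCurve] = {
    "winter_wheat": CropCurve(60.0, 140.0, 7.3, 227.0),
    "sugar_beet": CropCurve(105.0, 185.0, 6.6, 320.0),
    "maize": CropCurve(135.0, 190.0, 5.3, 269.0),
}

#: Crop shares of the arable area (the remainder is an "other/bare" class).
DEFAULT_CROP_PROPORTIONS: dict[str, float] = {
    "winter_wheat": 0.41,
    "sugar_beet": 0.28,
    "maize": 0.10,
}


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    Defaults describe the study conditions: mean field area 2.06 ha, crop
    shares 41/28/10 % of arable area, inter-field SD 1.0 LAI, intra-field
    pixel SD 0.2 LAI, no long-range background, NDVI endmembers 0.90/0.15
    and extinction coefficient 0.54.
    """

    rows: int = 600
    cols: int = 600
    resolution: float = 5.0  # m / pixel
    mean_field_area_m2: float = 20600.0  # 2.06 ha
    sigma_log_area: float = 0.8
    crop_proportions: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_CROP_PROPORTIONS)
    )
    crop_curves: dict[str, CropCurve] = dc_field(
        default_factory=lambda: dict(DEFAULT_CROP_CURVES)
    )
    inter_field_sd: float = 1.0  # LAI, SD of per-field offsets
    intra_field_sd: float = 0.2  # LAI, SD of pixel noise
    long_range_sill: float = 0.0  # LAI^2, variance of the background field
    long_range_m: float = 1000.0  # m, exponential covariance range parameter
    ndvi_v: float = 0.90
    ndvi_s: float = 0.15
    extinction_k: float = 0.54
    reflectance_noise_sd: float = 0.0
    forest_fraction: float = 0.04
    bare_fraction: float = 0.04
    forest_lai: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name, sd in [
            ("inter_field_sd", self.inter_field_sd),
            ("intra_field_sd", self.intra_field_sd),
            ("long_range_sill", self.long_range_sill),
            ("reflectance_noise_sd", self.reflectance_noise_sd),
        ]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        props = list(self.crop_proportions.values())
        if any(p < 0 or p > 1 for p in props) or sum(props) > 1 + 1e-9:
            raise ValueError("crop proportions must lie in [0,1] and sum to <= 1")
        if not (-1 <= self.ndvi_s < self.ndvi_v <= 1):
            raise ValueError("need -1 <= ndvi_s < ndvi_v <= 1")
        if set(self.crop_proportions) - set(self.crop_curves):
            raise ValueError("every crop with a proportion needs a curve")

    @property
    def crops(self) -> list[str]:
        return list(self.crop_proportions)

    def crop_code(self, crop: str) -> int:
        return self.crops.index(crop) + 1

    def code_to_crop(self) -> dict[int, str]:
        return {i + 1: c for i, c in enumerate(self.crops)}


@dataclass
class SceneTruth:
    """Ground truth of a generated scene.

    ``components`` holds the additive pieces of the most recently simulated
    date (crop curve value, field effect, long-range effect, pixel noise),
    keyed by name; true LAI is their clamped sum.
    """

    landuse: Raster
    field_labels: Raster
    field_crop: dict[int, int]  # field id -> land-use code
    field_pixels: dict[int, int]  # field id -> pixel count
    config: SceneConfig
    lai: Raster | None = None
    components: dict[str, np.ndarray] = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# mosaic construction
# ---------------------------------------------------------------------------

def _bsp_partition(
    rows: int, cols: int, n_fields: int, sigma: float, rng: np.random.Generator
) -> list[tuple[int, int, int, int]]:
    """Partition the grid into ``n_fields`` rectangles by recursive splits.

    Each rectangle carries the number of fields it must produce; a split
    divides both the rectangle (jittered position along its longer side)
    and the count (jittered around the area share).  The multiplicative
    cascade of jitters yields an approximately log-normal area spread whose
    width grows with ``sigma``, while the leaf count — and hence the mean
    field area — is exact.
    """
    jitter = min(0.45, 0.25 * sigma)
    leaves: list[tuple[int, int, int, int]] = []
    stack: list[tuple[int, int, int, int, int]] = [(0, rows, 0, cols, n_fields)]
    while stack:
        r0, r1, c0, c1, k = stack.pop()
        if k <= 1 or max(r1 - r0, c1 - c0) < 4:
            leaves.append((r0, r1, c0, c1))
            continue
        frac = 0.5 + rng.uniform(-jitter, jitter)
        if (r1 - r0) >= (c1 - c0):
            cut = min(max(r0 + int(round((r1 - r0) * frac)), r0 + 2), r1 - 2)
            a, b = (r0, cut, c0, c1), (cut, r1, c0, c1)
            share = (cut - r0) / (r1 - r0)
        else:
            cut = min(max(c0 + int(round((c1 - c0) * frac)), c0 + 2), c1 - 2)
            a, b = (r0, r1, c0, cut), (r0, r1, cut, c1)
            share = (cut - c0) / (c1 - c0)
        spread = sigma * np.sqrt(max(k * share * (1 - share), 0.25))
        k1 = int(round(k * share + spread * rng.standard_normal()))
        k1 = min(max(k1, 1), k - 1)
        stack.append((*a, k1))
        stack.append((*b, k - k1))
    return leaves


def _assign_classes(
    n_fields: int,
    areas: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign a land-use code to every field.

    Reference classes (forest, bare ground) first claim whole fields until
    their area fractions are met; arable fields are then assigned crops by a
    randomized largest-deficit rule so realized area shares track the
    configured proportions closely even for moderate field counts.
    """
    total = areas.sum()
    codes = np.full(n_fields, OTHER_ARABLE_CODE, dtype=np.int32)
    order = rng.permutation(n_fields)

    cursor = 0
    for ref_code, frac in [
        (FOREST_CODE, config.forest_fraction),
        (BARE_CODE, config.bare_fraction),
    ]:
        acc = 0.0
        while acc < frac * total and cursor < n_fields:
            fid = order[cursor]
            codes[fid] = ref_code
            acc += areas[fid]
            cursor += 1

    arable = order[cursor:]
    arable_area = areas[arable].sum()
    crop_codes = [config.crop_code(c) for c in config.crops]
    targets = np.array([config.crop_proportions[c] for c in config.crops])
    deficits = targets * arable_area
    for fid in arable:
        if deficits.max() <= 0:
            break  # remainder stays "other arable"
        k = int(np.argmax(deficits))
        codes[fid] = crop_codes[k]
        deficits[k] -= areas[fid]
    return codes


def generate_mosaic(config: SceneConfig) -> SceneTruth:
    """Generate land use and field labels for a scene (no LAI yet).

    Raises ``ValueError`` if the domain holds fewer than 20 fields at the
    configured mean field area.
    """
    px_area = config.resolution ** 2
    n_fields = int(round(config.rows * config.cols * px_area / config.mean_field_area_m2))
    if n_fields < 20:
        raise ValueError(
            f"domain holds only {n_fields} fields at mean area "
            f"{config.mean_field_area_m2} m^2; need >= 20"
        )
    rng = np.random.default_rng([config.seed, 100])
    leaves = _bsp_partition(config.rows, config.cols, n_fields, config.sigma_log_area, rng)
    # row-major order of the top-left pixel -> stable field ids
    leaves.sort(key=lambda b: (b[0], b[2]))

    areas = np.array([(r1 - r0) * (c1 - c0) * px_area for r0, r1, c0, c1 in leaves])
    codes = _assign_classes(len(leaves), areas, config, rng)

    landuse = np.zeros((config.rows, config.cols), dtype=np.int32)
    labels = np.zeros((config.rows, config.cols), dtype=np.int32)
    field_crop: dict[int, int] = {}
    field_pixels: dict[int, int] = {}
    for i, (r0, r1, c0, c1) in enumerate(leaves):
        fid = i + 1
        landuse[r0:r1, c0:c1] = codes[i]
        labels[r0:r1, c0:c1] = fid
        field_crop[fid] = int(codes[i])
        field_pixels[fid] = (r1 - r0) * (c1 - c0)

    return SceneTruth(
        landuse=Raster(landuse, config.resolution, NODATA_CLASS, "landuse"),
        field_labels=Raster(labels, config.resolution, 0, "labels"),
        field_crop=field_crop,
        field_pixels=field_pixels,
        config=config,
    )


# ---------------------------------------------------------------------------
# Gaussian random field (exponential covariance) by circulant embedding
# ---------------------------------------------------------------------------

def gaussian_random_field(
    rows: int,
    cols: int,
    resolution: float,
    sill: float,
    range_m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean stationary Gaussian field with covariance ``sill * exp(-h/range_m)``.

    Simulated by circulant embedding on a 2x-padded torus: the covariance
    kernel is diagonalized by the 2-D FFT, its (clipped) eigenvalue square
    root filters white noise.  With 2x padding the exponential kernel's
    negative eigenvalues are negligible.
    """
    if sill == 0:
        return np.zeros((rows, cols))
    m = next_fast_len(2 * rows)
    n = next_fast_len(2 * cols)
    di = np.minimum(np.arange(m), m - np.arange(m)) * resolution
    dj = np.minimum(np.arange(n), n - np.arange(n)) * resolution
    dist = np.sqrt(di[:, None] ** 2 + dj[None, :] ** 2)
    cov = sill * np.exp(-dist / range_m)
    lam = fft2(cov).real
    np.maximum(lam, 0.0, out=lam)
    white = rng.standard_normal((m, n))
    z = ifft2(np.sqrt(lam) * fft2(white)).real
    return np.ascontiguousarray(z[:rows, :cols])


# ---------------------------------------------------------------------------
# LAI simulation and the forward sensor model
# ---------------------------------------------------------------------------

def simulate_lai(truth: SceneTruth, config: SceneConfig, day: float) -> Raster:
    """True LAI on day-of-year ``day``: crop curve + field effect +
    long-range background + pixel noise, clamped at zero.

    Field and background effects are keyed by the scene seed only, so they
    persist across dates (they emulate soil and site quality); pixel noise
    is resampled per date.
    """
    if not (1 <= day <= 366):
        raise ValueError(f"day-of-year {day} outside [1, 366]")

    landuse = truth.landuse.data
    labels = truth.field_labels.data
    code_to_crop = config.code_to_crop()

    curve = np.zeros(landuse.shape)
    for code, crop in code_to_crop.items():
        curve[landuse == code] = config.crop_curves[crop](day)
    curve[landuse == FOREST_CODE] = config.forest_lai

    # per-field offsets, sampled once per field id under the scene seed
    rng_field = np.random.default_rng([config.seed, 101])
    max_label = int(labels.max())
    offsets = rng_field.normal(0.0, config.inter_field_sd, size=max_label + 1)
    offsets[0] = 0.0
    field_eff = offsets[labels]

    rng_bg = np.random.default_rng([config.seed, 102])
    long_eff = gaussian_random_field(
        *landuse.shape, config.resolution, config.long_range_sill,
        config.long_range_m, rng_bg,
    )

    rng_noise = np.random.default_rng([config.seed, 103, int(day)])
    noise = rng_noise.normal(0.0, config.intra_field_sd, size=landuse.shape)

    arable = np.isin(landuse, [config.crop_code(c) for c in config.crops] + [OTHER_ARABLE_CODE])
    lai = np.where(
        arable,
        np.maximum(curve + field_eff + long_eff + noise, 0.0),
        curve,  # forest constant, bare 0
    )

    truth.components = {
        "curve": curve,
        "field_effect": np.where(arable, field_eff, 0.0),
        "long_range": np.where(arable, long_eff, 0.0),
        "noise": np.where(arable, noise, 0.0),
    }
    truth.lai = Raster(lai, config.resolution, semantic="lai")
    return truth.lai


def forward_ndvi(
    lai: Raster,
    config: SceneConfig,
    landuse: Raster | None = None,
    red_baseline: float = 0.05,
) -> tuple[Raster, Raster]:
    """Forward sensor model: LAI -> (NIR, Red) reflectances.

    FVC = 1 - exp(-k LAI); NDVI = NDVI_s + FVC (NDVI_v - NDVI_s); Red is a
    fixed baseline and NIR solves the NDVI definition.  Optional Gaussian
    reflectance noise (``config.reflectance_noise_sd``) is added per band.
    When ``landuse`` is given, reference patches sit exactly at the
    endmembers (forest at NDVI_v, bare ground at NDVI_s) so that per-date
    endmember estimation from the scene is unbiased.  Noiseless output
    round-trips exactly through the retrieval chain.
    """
    fvc = 1.0 - np.exp(-config.extinction_k * lai.data)
    ndvi = config.ndvi_s + fvc * (config.ndvi_v - config.ndvi_s)
    if landuse is not None:
        ndvi[landuse.data == FOREST_CODE] = config.ndvi_v
        ndvi[landuse.data == BARE_CODE] = config.ndvi_s
    red = np.full_like(ndvi, red_baseline)
    nir = red * (1.0 + ndvi) / (1.0 - ndvi)
    if config.reflectance_noise_sd > 0:
        rng = np.random.default_rng([config.seed, 104])
        nir = nir + rng.normal(0.0, config.reflectance_noise_sd, nir.shape)
        red = red + rng.normal(0.0, config.reflectance_noise_sd, red.shape)
        np.clip(nir, 1e-6, 1.0, out=nir)
        np.clip(red, 1e-6, 1.0, out=red)
    res = lai.resolution
    return (
        Raster(nir, res, semantic="reflectance"),
        Raster(red, res, semantic="reflectance"),
    )
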