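"""LAI retrieval from two-band reflectance.

The chain NDVI -> fractional vegetation cover (FVC) -> LAI:

    NDVI = (NIR - Red) / (NIR + Red)
    FVC  = (NDVI - NDVI_s) / (NDVI_v - NDVI_s)
    LAI  = -ln(1 - FVC) / k

with NDVI endmembers (NDVI_v fully vegetated, NDVI_s bare soil) estimated
per date from permanently vegetated (broadleaf forest) and permanently bare
reference areas by a histogram-mode analysis.  k is the Beer-Lambert light
extinction coefficient (default 0.54).  NDVI below the soil endmember gives
negative FVC and is mapped to LAI 0; FVC is truncated so LAI never exceeds
the configured cap (default 7.0, the upper end of the plausible crop range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import NODATA_FLOAT, Raster, require_congruent

__all__ = [
    "Endmembers",
    "RetrievalParams",
    "compute_ndvi",
    "estimate_endmembers",
    "ndvi_to_fvc",
    "fvc_to_lai",
    "retrieve_lai",
]

_HIST_BIN = 0.01  # NDVI bin width for the endmember histogram analysis


@dataclass(frozen=True)
class Endmembers:
    """Per-date NDVI endmembers: fully vegetated (v) and bare soil (s)."""

    ndvi_v: float
    ndvi_s: float
    date: str = ""

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ndvi_s < self.ndvi_v <= 1.0):
            raise ValueError(
                f"endmembers must satisfy -1 <= ndvi_s < ndvi_v <= 1, got "
                f"ndvi_s={self.ndvi_s}, ndvi_v={self.ndvi_v}"
            )


@dataclass(frozen=True)
class RetrievalParams:
    """Extinction coefficient, LAI cap, and negative-LAI handling."""

    k: float = 0.54
    lai_cap: float = 7.0
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0 or self.lai_cap <= 0:
            raise ValueError("k and lai_cap must be positive")

    @property
    def fvc_cap(self) -> float:
        """FVC at which LAI reaches the cap."""
        return 1.0 - np.exp(-self.k * self.lai_cap)


def compute_ndvi(nir: Raster, red: Raster) -> Raster:
    """Normalized difference vegetation index (NIR - Red)/(NIR + Red).

    Nodata in either band propagates; a zero band sum yields nodata.
    """
    require_congruent(nir, red)
    valid = nir.valid_mask() & red.valid_mask()
    total = nir.data + red.data
    valid &= total != 0
    ndvi = np.full(nir.shape, NODATA_FLOAT)
    ndvi[valid] = (nir.data[valid] - red.data[valid]) / total[valid]
    return Raster(ndvi, nir.resolution, NODATA_FLOAT, "ndvi")


def _histogram_mode(values: np.ndarray, tie_high: bool) -> float:
    """Mode of a fixed-width (0.01) histogram.

    Returns the mean of the values inside the modal bin (so a degenerate
    histogram recovers the exact value).  Ties go to the higher bin for the
    vegetated endmember and to the lower bin for the soil endmember.
    """
    idx = np.floor((values + 1.0) / _HIST_BIN + 1e-9).astype(np.int64)  # anchor at -1
    counts = np.bincount(idx)
    best = np.flatnonzero(counts == counts.max())
    bin_i = best.max() if tie_high else best.min()
    return float(values[idx == bin_i].mean())


def estimate_endmembers(
    ndvi: Raster,
    landuse: Raster,
    forest_code: int,
    bare_code: int,
    date: str = "",
    min_pixels: int = 100,
) -> Endmembers:
    """Estimate per-date endmembers from reference land-cover classes.

    ndvi_v is the histogram mode of the forest-class NDVI, ndvi_s the mode
    of the bare-ground-class NDVI (bin width 0.01).
    """
    require_congruent(ndvi, landuse)
    valid = ndvi.valid_mask()
    forest = ndvi.data[valid & (landuse.data == forest_code)]
    bare = ndvi.data[valid & (landuse.data == bare_code)]
    if forest.size < min_pixels or bare.size < min_pixels:
        raise ValueError(
            f"need >= {min_pixels} valid reference pixels per class, got "
            f"forest={forest.size}, bare={bare.size}"
        )
    ndvi_v = _histogram_mode(forest, tie_high=True)
    ndvi_s = _histogram_mode(bare, tie_high=False)
    if ndvi_v <= ndvi_s:
        raise ValueError(
            f"inconsistent endmembers: ndvi_v={ndvi_v} <= ndvi_s={ndvi_s}"
        )
    return Endmembers(ndvi_v=ndvi_v, ndvi_s=ndvi_s, date=date)


def ndvi_to_fvc(
    ndvi: Raster, em: Endmembers, params: RetrievalParams = RetrievalParams()
) -> Raster:
    """Linear NDVI unmixing to fractional vegetation cover.

    Values may fall outside [0, 1]; FVC above the cap implied by the LAI cap
    is truncated so the subsequent log inversion stays finite.
    """
    valid = ndvi.valid_mask()
    fvc = np.full(ndvi.shape, NODATA_FLOAT)
    fvc[valid] = (ndvi.data[valid] - em.ndvi_s) / (em.ndvi_v - em.ndvi_s)
    fvc[valid & (fvc > params.fvc_cap)] = params.fvc_cap
    return Raster(fvc, ndvi.resolution, NODATA_FLOAT, "fvc")


def fvc_to_lai(fvc: Raster, params: RetrievalParams = RetrievalParams()) -> Raster:
    """Beer-Lambert inversion LAI = -ln(1 - FVC)/k.

    Negative FVC (NDVI below the soil endmember) maps to LAI 0.
    """
    valid = fvc.valid_mask()
    lai = np.full(fvc.shape, NODATA_FLOAT)
    f = np.clip(fvc.data[valid], None, params.fvc_cap)
    with np.errstate(invalid="ignore"):
        vals = -np.log1p(-f) / params.k
    if params.clamp_negative:
        vals = np.maximum(vals, 0.0)
    lai[valid] = vals
    return Raster(lai, fvc.resolution, NODATA_FLOAT, "lai")


def retrieve_lai(
    nir: Raster,
    red: Raster,
    em: Endmembers,
    params: RetrievalParams = RetrievalParams(),
) -> Raster:
    """Full retrieval chain reflectance -> NDVI -> FVC -> LAI."""
    ndvi = compute_ndvi(nir, red)
    fvc = ndvi_to_fvc(ndvi, em, params)
    return fvc_to_lai(fvc, params)
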