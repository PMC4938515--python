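"""Minimal raster container and TIFF I/O.

A :class:`Raster` is a rectangular grid of values with a ground resolution
(m/pixel), a nodata sentinel and a semantic tag (``"reflectance"``,
``"ndvi"``, ``"lai"``, ``"landuse"``, ``"labels"``, ``"mask"``).  Continuous
products use ``-9999.0`` as nodata, categorical products use ``0``.
Files are written as single-band TIFF with a JSON sidecar carrying
resolution/nodata/semantic, so round-trips preserve the full container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

NODATA_FLOAT = -9999.0
NODATA_CLASS = 0

__all__ = ["Raster", "NODATA_FLOAT", "NODATA_CLASS", "read_raster", "write_raster"]


@dataclass
class Raster:
    """A single-band raster with resolution, nodata and a semantic tag."""

    data: np.ndarray
    resolution: float
    nodata: float = NODATA_FLOAT
    semantic: str = "generic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels that are not nodata (NaN counts as nodata)."""
        m = self.data != self.nodata
        if np.issubdtype(self.data.dtype, np.floating):
            m &= ~np.isnan(self.data)
        return m

    def valid_values(self) -> np.ndarray:
        return self.data[self.valid_mask()]

    def congruent(self, other: "Raster") -> bool:
        return self.shape == other.shape and self.resolution == other.resolution

    def with_data(self, data: np.ndarray, semantic: str | None = None) -> "Raster":
        out = replace(self, data=data)
        if semantic is not None:
            out.semantic = semantic
        return out

    def pixel_area(self) -> float:
        """Ground area of one pixel in m^2."""
        return self.resolution ** 2


def require_congruent(*rasters: Raster) -> None:
    """Raise ``ValueError`` unless all rasters share grid shape and resolution."""
    first = rasters[0]
    for r in rasters[1:]:
        if not first.congruent(r):
            raise ValueError(
                f"rasters not congruent: {first.shape}@{first.resolution} m vs "
                f"{r.shape}@{r.resolution} m"
            )


def write_raster(raster: Raster, path: str | Path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, raster.data)
    meta = {
        "resolution": raster.resolution,
        "nodata": raster.nodata,
        "semantic": raster.semantic,
        "dtype": str(raster.data.dtype),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path: str | Path) -> Raster:
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:  # bare TIFF: assume 1 m continuous raster
        meta = {"resolution": 1.0, "nodata": NODATA_FLOAT, "semantic": "generic"}
    return Raster(
        data=data,
        resolution=float(meta["resolution"]),
        nodata=meta["nodata"],
        semantic=meta.get("semantic", "generic"),
    )
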