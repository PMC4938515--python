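"""Land-use handling and field segmentation.

Coarsens categorical land-use rasters by majority resampling, removes
potentially mixed pixels (cells whose neighborhood is not uniform in land
use), segments the remaining area into individual fields as connected
components of uniform class, filters out fields too small for statistics,
and flags pixels whose LAI is implausible for their land use and date
(e.g. substantial LAI on a maize pixel in February).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster, require_congruent

__all__ = [
    "FieldMap",
    "CropCalendar",
    "upscale_majority",
    "mask_mixed_pixels",
    "segment_fields",
    "filter_fields_by_size",
    "plausibility_filter",
]


@dataclass
class FieldMap:
    """Labeled fields: a positive-integer label raster plus per-field records.

    Label 0 marks pixels belonging to no field.  ``records`` is a DataFrame
    with columns id, code, pixels, area_m2, row, col (centroid grid coords).
    """

    labels: Raster
    records: pd.DataFrame

    @property
    def n_fields(self) -> int:
        return len(self.records)

    def field_codes(self) -> dict[int, int]:
        return dict(zip(self.records["id"], self.records["code"]))

    def total_area(self) -> float:
        return float(self.records["area_m2"].sum())


@dataclass
class CropCalendar:
    """Per-crop plausibility windows: (day_start, day_end, max plausible LAI).

    A pixel is implausible when its LAI exceeds the window maximum for its
    crop on the given day; absence of a window imposes no constraint.
    """

    windows: dict[int, list[tuple[float, float, float]]] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, wins in self.windows.items():
            ordered = sorted(wins)
            for (s0, e0, m0), (s1, e1, m1) in zip(ordered, ordered[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping windows for crop code {code}")
            if any(m < 0 for _, _, m in wins):
                raise ValueError("max plausible LAI must be >= 0")

    def max_lai(self, code: int, day: float) -> float | None:
        for start, end, max_lai in self.windows.get(code, []):
            if start <= day <= end:
                return max_lai
        return None

    @classmethod
    def pre_emergence(
        cls, emergence_days: dict[int, float], max_lai: float = 0.3
    ) -> "CropCalendar":
        """Calendar flagging LAI above ``max_lai`` before each crop's emergence."""
        return cls(
            {code: [(1.0, day, max_lai)] for code, day in emergence_days.items()}
        )


def upscale_majority(landuse: Raster, factor: int) -> Raster:
    """Coarsen a class raster by assigning each block its most frequent class.

    Nodata is ignored within a block (an all-nodata block stays nodata);
    ties break toward the lowest class code.  Dimensions not divisible by
    ``factor`` are padded with nodata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return landuse
    data = landuse.data
    nodata = landuse.nodata
    rows = -(-data.shape[0] // factor) * factor
    cols = -(-data.shape[1] // factor) * factor
    if (rows, cols) != data.shape:
        padded = np.full((rows, cols), nodata, dtype=data.dtype)
        padded[: data.shape[0], : data.shape[1]] = data
        data = padded
    blocks = data.reshape(rows // factor, factor, cols // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(rows // factor, cols // factor, -1)

    out = np.full(blocks.shape[:2], nodata, dtype=data.dtype)
    classes = np.unique(data)
    classes = classes[classes != nodata]
    best_count = np.zeros(blocks.shape[:2], dtype=np.int64)
    # iterate classes in increasing code order; strict > implements the
    # lowest-code tie-break
    for cls_code in classes:
        count = (blocks == cls_code).sum(axis=2)
        win = count > best_count
        out[win] = cls_code
        best_count[win] = count[win]
    return Raster(out, landuse.resolution * factor, nodata, landuse.semantic)


def mask_mixed_pixels(landuse: Raster, connectivity: int = 8) -> Raster:
    """Keep only pixels whose whole neighborhood shares their land-use class.

    With the default Moore (8-) neighborhood a pixel survives iff all 8
    neighbors exist (edge pixels are dropped) and carry the same class; the
    result is continuous uniform-class areas separated by removed borders.
    Nodata pixels are never kept.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    data = landuse.data
    keep = np.zeros(data.shape, dtype=bool)
    if min(data.shape) >= 3:
        center = data[1:-1, 1:-1]
        inner = np.ones(center.shape, dtype=bool)
        offsets = (
            [(-1, 0), (1, 0), (0, -1), (0, 1)]
            if connectivity == 4
            else [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
        )
        for dr, dc in offsets:
            inner &= data[1 + dr : data.shape[0] - 1 + dr, 1 + dc : data.shape[1] - 1 + dc] == center
        inner &= center != landuse.nodata
        keep[1:-1, 1:-1] = inner
    return Raster(keep, landuse.resolution, nodata=False, semantic="mask")


def segment_fields(landuse: Raster, mask: Raster, connectivity: int = 4) -> FieldMap:
    """Segment kept pixels into fields: connected components of uniform class.

    Components are 4-connected by default; ids are assigned in row-major
    order of each component's first pixel.  Adjacent fields of the same
    class that touch (despite the mixed-pixel borders) merge into one field
    by construction.
    """
    require_congruent(landuse, mask)
    structure = (
        ndimage.generate_binary_structure(2, 1)
        if connectivity == 4
        else ndimage.generate_binary_structure(2, 2)
    )
    keep = mask.data.astype(bool) & (landuse.data != landuse.nodata)
    labels = np.zeros(landuse.shape, dtype=np.int32)
    next_id = 1
    recs = []
    res2 = landuse.resolution ** 2
    for cls_code in np.unique(landuse.data[keep]):
        cls_mask = keep & (landuse.data == cls_code)
        lab, n = ndimage.label(cls_mask, structure=structure)
        if n == 0:
            continue
        labels[cls_mask] = lab[cls_mask] + (next_id - 1)
        counts = np.bincount(lab[cls_mask])[1:]
        rows_idx, cols_idx = np.nonzero(cls_mask)
        comp = lab[cls_mask]
        r_cent = np.bincount(comp, weights=rows_idx)[1:] / counts
        c_cent = np.bincount(comp, weights=cols_idx)[1:] / counts
        for j in range(n):
            recs.append(
                dict(
                    id=next_id + j,
                    code=int(cls_code),
                    pixels=int(counts[j]),
                    area_m2=float(counts[j] * res2),
                    row=float(r_cent[j]),
                    col=float(c_cent[j]),
                )
            )
        next_id += n
    records = pd.DataFrame(
        recs, columns=["id", "code", "pixels", "area_m2", "row", "col"]
    )
    if len(records):
        # reassign ids in row-major order of each component's first pixel
        uniq, first_idx = np.unique(labels.ravel(), return_index=True)
        nz = uniq > 0
        old_ids = uniq[nz][np.argsort(first_idx[nz])]
        remap_arr = np.zeros(int(labels.max()) + 1, dtype=np.int32)
        remap_arr[old_ids] = np.arange(1, len(old_ids) + 1, dtype=np.int32)
        labels = remap_arr[labels]
        records["id"] = records["id"].map(
            {int(o): i + 1 for i, o in enumerate(old_ids)}
        )
        records = records.sort_values("id").reset_index(drop=True)
    label_raster = Raster(labels, landuse.resolution, 0, "labels")
    return FieldMap(labels=label_raster, records=records)


def filter_fields_by_size(
    fm: FieldMap, threshold: float | str = "median"
) -> tuple[FieldMap, dict]:
    """Drop fields with area <= threshold (m^2); "median" uses the median area.

    Returns the filtered FieldMap and a report with the number removed and
    the percentage of area removed (kept% + removed% = 100 exactly).
    """
    if fm.n_fields == 0:
        return fm, {"threshold_m2": 0.0, "n_removed": 0, "area_removed_pct": 0.0}
    if isinstance(threshold, str):
        if threshold != "median":
            raise ValueError(f"unknown threshold {threshold!r}")
        thr = float(np.median(fm.records["area_m2"]))
    else:
        thr = float(threshold)
        if thr < 0:
            raise ValueError("threshold must be >= 0")
    keep = fm.records["area_m2"] > thr
    removed_area = float(fm.records.loc[~keep, "area_m2"].sum())
    total_area = fm.total_area()
    kept_ids = set(fm.records.loc[keep, "id"])
    labels = fm.labels.data.copy()
    labels[~np.isin(labels, list(kept_ids))] = 0
    new_fm = FieldMap(
        labels=fm.labels.with_data(labels),
        records=fm.records.loc[keep].reset_index(drop=True),
    )
    report = {
        "threshold_m2": thr,
        "n_removed": int((~keep).sum()),
        "area_removed_pct": 100.0 * removed_area / total_area if total_area else 0.0,
    }
    return new_fm, report


def plausibility_filter(
    lai: Raster, landuse: Raster, cal: CropCalendar, day: float
) -> Raster:
    """Keep-mask flagging pixels whose LAI is impossible for their land use.

    A pixel is dropped iff its crop has a plausibility window covering
    ``day`` and its LAI exceeds that window's maximum.  The mask applies to
    per-crop analyses only; overall-arable-area statistics ignore it.
    A land-use code present in the raster but absent from the calendar is a
    configuration error; a code registered with no window covering ``day``
    is simply unconstrained (kept).
    """
    require_congruent(lai, landuse)
    keep = np.ones(lai.shape, dtype=bool)
    valid = lai.valid_mask()
    for code in np.unique(landuse.data[valid]):
        if code == landuse.nodata:
            continue
        if int(code) not in cal.windows:
            raise KeyError(
                f"land-use code {int(code)} has no crop-calendar entry; "
                "register it (an empty window list means unconstrained)"
            )
        max_lai = cal.max_lai(int(code), day)
        if max_lai is None:
            continue
        sel = valid & (landuse.data == code)
        keep[sel & (lai.data > max_lai)] = False
    return Raster(keep, lai.resolution, nodata=False, semantic="mask")
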