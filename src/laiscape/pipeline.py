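"""End-to-end orchestration.

Runs the whole analysis on a synthetic scene (or user rasters): generate or
ingest reflectance + land use, retrieve LAI through per-date endmember
estimation, remove potentially mixed pixels, segment fields and filter them
by size, compute per-crop and overall variability statistics (means, SDs via
pooled variance, RFDs, accordance against field means and against a normal
comparator) and per-crop plus overall semivariogram structure with
abundance rebalancing.  All randomness derives from a single run seed via
named substreams, so re-running a configuration is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fields as fld
from . import retrieval as ret
from . import stats as st
from . import variogram as vg
from .raster import Raster, read_raster
from .synthetic import (
    BARE_CODE,
    FOREST_CODE,
    OTHER_ARABLE_CODE,
    SceneConfig,
    SceneTruth,
    forward_ndvi,
    generate_mosaic,
    simulate_lai,
)

__all__ = ["RunConfig", "HeterogeneityReport", "run_pipeline", "compare_datasets"]

# named substreams of the master seed, one per stochastic stage
_STREAM_SUBSAMPLE = 1
_STREAM_REBALANCE = 2


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``mode`` is ``"synthetic"`` (a :class:`SceneConfig` drives generation)
    or ``"rasters"`` (paths to NIR/Red/land-use TIFFs per date).  Dates are
    day-of-year values.  ``crop_weights`` are abundance fractions of the
    analyzed crops from the original classification; they are renormalized
    over the analyzed crops for pooled statistics.
    """

    mode: str = "synthetic"
    scene: SceneConfig = dc_field(default_factory=SceneConfig)
    dates: list[int] = dc_field(default_factory=lambda: [175])
    raster_inputs: list[dict] = dc_field(default_factory=list)  # raster mode
    class_width: float = st.DEFAULT_CLASS_WIDTH
    lag_width: float = 200.0
    max_lag: float = 25_000.0
    subsample_fraction: float = 0.005
    size_threshold: float | str = "median"
    retrieval: ret.RetrievalParams = dc_field(default_factory=ret.RetrievalParams)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "rasters"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.dates:
            raise ValueError("at least one analysis date is required")
        if self.mode == "rasters":
            for entry in self.raster_inputs:
                for key in ("nir", "red"):
                    if not Path(entry[key]).exists():
                        raise FileNotFoundError(
                            f"raster input does not exist: {entry[key]}"
                        )


@dataclass
class HeterogeneityReport:
    """Machine-readable result bundle: a nested dict plus CSV side-tables."""

    per_date: dict = dc_field(default_factory=dict)
    field_table: pd.DataFrame | None = None
    config_summary: dict = dc_field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config_summary, "dates": self.per_date},
            indent=2,
            sort_keys=True,
            default=_jsonify,
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        if self.field_table is not None:
            self.field_table.to_csv(out / "field_stats.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _crop_variogram(
    lai: Raster,
    mask: np.ndarray,
    config: RunConfig,
    stream: np.random.SeedSequence,
) -> dict:
    pts = vg.subsample_points(lai, config.subsample_fraction, stream, mask=mask)
    if pts.shape[0] < 2:
        return {"n_points": int(pts.shape[0]), "model": vg.failed_fit().to_dict()}
    ev = vg.empirical_variogram(pts, config.lag_width, config.max_lag)
    model = vg.fit_variogram_ladder(ev)
    return {"n_points": int(pts.shape[0]), "model": model.to_dict()}


def run_pipeline(config: RunConfig) -> HeterogeneityReport:
    """Execute the full analysis; see the module docstring for the stages."""
    master = np.random.SeedSequence(config.seed)
    sub_streams = {
        "subsample": master.spawn(1)[0],
        "rebalance": master.spawn(1)[0],
    }

    if config.mode == "synthetic":
        scene_cfg = config.scene
        truth: SceneTruth | None = generate_mosaic(scene_cfg)
        landuse = truth.landuse
        crop_codes = {c: scene_cfg.crop_code(c) for c in scene_cfg.crops}
        crop_weights = dict(scene_cfg.crop_proportions)
        emergence = {
            scene_cfg.crop_code(c): curve.emergence_day
            for c, curve in scene_cfg.crop_curves.items()
            if c in crop_codes
        }
    else:
        truth = None
        landuse = read_raster(config.raster_inputs[0]["landuse"])
        codes = sorted(
            int(c) for c in np.unique(landuse.valid_values())
            if c not in (FOREST_CODE, BARE_CODE, OTHER_ARABLE_CODE)
        )
        crop_codes = {f"crop_{c}": c for c in codes}
        crop_weights = {name: 1.0 / len(codes) for name in crop_codes}
        emergence = {}

    calendar = fld.CropCalendar.pre_emergence(emergence)
    for code in (OTHER_ARABLE_CODE, FOREST_CODE, BARE_CODE):
        calendar.windows.setdefault(code, [])

    # segmentation is date-independent
    keep = fld.mask_mixed_pixels(landuse)
    fmap = fld.segment_fields(landuse, keep)
    fmap, size_report = fld.filter_fields_by_size(fmap, config.size_threshold)

    report = HeterogeneityReport(
        config_summary={
            "mode": config.mode,
            "seed": config.seed,
            "class_width": config.class_width,
            "lag_width_m": config.lag_width,
            "max_lag_m": config.max_lag,
            "subsample_fraction": config.subsample_fraction,
            "size_filter": size_report,
            "n_fields": fmap.n_fields,
        }
    )

    arable_codes = list(crop_codes.values())
    weights_arr = np.array([crop_weights[c] for c in crop_codes])
    weights_arr = weights_arr / weights_arr.sum()

    field_tables = []
    for idx, day in enumerate(config.dates):
        if config.mode == "synthetic":
            true_lai = simulate_lai(truth, config.scene, day)
            nir, red = forward_ndvi(true_lai, config.scene, landuse=landuse)
        else:
            entry = config.raster_inputs[idx]
            nir, red = read_raster(entry["nir"]), read_raster(entry["red"])
        ndvi = ret.compute_ndvi(nir, red)
        em = ret.estimate_endmembers(ndvi, landuse, FOREST_CODE, BARE_CODE, date=str(day))
        fvc = ret.ndvi_to_fvc(ndvi, em, config.retrieval)
        lai = ret.fvc_to_lai(fvc, config.retrieval)

        plaus = fld.plausibility_filter(lai, landuse, calendar, day)
        aggregates = st.field_aggregates(lai, fmap)
        field_tables.append(aggregates.assign(date=day))

        date_entry: dict = {
            "endmembers": {"ndvi_v": em.ndvi_v, "ndvi_s": em.ndvi_s},
            "crops": {},
        }

        crop_means, crop_sds, crop_counts = [], [], []
        crop_rfds, crop_field_rfds = [], []
        for name, code in crop_codes.items():
            pix_mask = (
                landuse.data == code
            ) & lai.valid_mask() & keep.data.astype(bool) & plaus.data.astype(bool)
            vals = lai.data[pix_mask]
            crop_fields = aggregates[
                (aggregates["code"] == code) & ~aggregates["missing"]
            ]
            if vals.size == 0:
                date_entry["crops"][name] = {"n_pixels": 0}
                crop_means.append(0.0)
                crop_sds.append(0.0)
                crop_counts.append(0)
                crop_rfds.append(None)
                crop_field_rfds.append(None)
                continue
            rfd = st.build_rfd(vals, config.class_width)
            fm_vals = np.repeat(
                crop_fields["mean"].to_numpy(), crop_fields["n"].to_numpy()
            )
            rfd_fm = st.build_rfd(fm_vals, config.class_width) if fm_vals.size else None
            mean, sd = float(vals.mean()), float(vals.std())
            entry_c = {
                "n_pixels": int(vals.size),
                "n_fields": int(len(crop_fields)),
                "mean": mean,
                "sd": sd,
                "accordance_pixel_vs_fieldmean": (
                    st.accordance(rfd, rfd_fm) if rfd_fm is not None else None
                ),
                "accordance_pixel_vs_normal": (
                    st.accordance(rfd, st.normal_reference_rfd(mean, sd, config.class_width))
                    if sd > 0
                    else None
                ),
                "variogram": _crop_variogram(
                    lai, pix_mask, config, sub_streams["subsample"].spawn(1)[0]
                ),
            }
            date_entry["crops"][name] = entry_c
            crop_means.append(mean)
            crop_sds.append(sd)
            crop_counts.append(vals.size)
            crop_rfds.append(rfd)
            crop_field_rfds.append(rfd_fm)

        # overall arable area: weighted over analyzed crops, plausibility
        # filter intentionally NOT applied
        cstats = st.CropStats(
            crops=list(crop_codes),
            means=np.array(crop_means),
            sds=np.array(crop_sds),
            counts=np.array(crop_counts),
            weights=weights_arr,
        )
        o_mean, o_sd = st.overall_stats(cstats)
        usable = [r for r in crop_rfds if r is not None]
        overall_entry: dict = {"mean": o_mean, "sd": o_sd}
        if usable:
            w_use = weights_arr[[r is not None for r in crop_rfds]]
            overall_rfd = st.weighted_rfd(usable, w_use)
            usable_fm = [r for r in crop_field_rfds if r is not None]
            if usable_fm:
                w_fm = weights_arr[[r is not None for r in crop_field_rfds]]
                overall_entry["accordance_pixel_vs_fieldmean"] = st.accordance(
                    overall_rfd, st.weighted_rfd(usable_fm, w_fm)
                )
            if o_sd > 0:
                overall_entry["accordance_pixel_vs_normal"] = st.accordance(
                    overall_rfd,
                    st.normal_reference_rfd(o_mean, o_sd, config.class_width),
                )
        # overall variogram on rebalanced arable pixels
        arable_mask = np.isin(landuse.data, arable_codes) & lai.valid_mask() & keep.data.astype(bool)
        rows, cols = np.nonzero(arable_mask)
        codes_here = landuse.data[rows, cols]
        targets = {code: float(w) for code, w in zip(crop_codes.values(), weights_arr)}
        try:
            kept_idx = vg.rebalance_abundance(
                codes_here, targets, sub_streams["rebalance"].spawn(1)[0]
            )
            bal = np.zeros_like(arable_mask)
            bal[rows[kept_idx], cols[kept_idx]] = True
            overall_entry["variogram"] = _crop_variogram(
                lai, bal, config, sub_streams["subsample"].spawn(1)[0]
            )
        except ValueError:
            overall_entry["variogram"] = None
        date_entry["overall"] = overall_entry
        report.per_date[str(day)] = date_entry

    report.field_table = pd.concat(field_tables, ignore_index=True)
    if config.output_dir:
        report.write(config.output_dir)
    return report


def compare_datasets(
    lai_a: Raster,
    lai_b: Raster,
    landuse: Raster,
    crop_codes: dict[str, int],
    class_width: float = st.DEFAULT_CLASS_WIDTH,
) -> pd.DataFrame:
    """Pairwise accordance and SD differences between two LAI sources.

    Both rasters must share the grid; rows cover each crop plus the pooled
    arable area (equal weights of the listed crops).
    """
    from .raster import require_congruent

    require_congruent(lai_a, lai_b, landuse)
    rows = []
    all_mask_a = np.zeros(lai_a.shape, bool)
    for name, code in crop_codes.items():
        mask = (landuse.data == code) & lai_a.valid_mask() & lai_b.valid_mask()
        all_mask_a |= mask
        if not mask.any():
            continue
        va, vb = lai_a.data[mask], lai_b.data[mask]
        rows.append(
            {
                "group": name,
                "accordance": st.accordance(
                    st.build_rfd(va, class_width), st.build_rfd(vb, class_width)
                ),
                "sd_a": float(va.std()),
                "sd_b": float(vb.std()),
                "sd_diff": float(va.std() - vb.std()),
            }
        )
    if all_mask_a.any():
        va, vb = lai_a.data[all_mask_a], lai_b.data[all_mask_a]
        rows.append(
            {
                "group": "overall",
                "accordance": st.accordance(
                    st.build_rfd(va, class_width), st.build_rfd(vb, class_width)
                ),
                "sd_a": float(va.std()),
                "sd_b": float(vb.std()),
                "sd_diff": float(va.std() - vb.std()),
            }
        )
    return pd.DataFrame(rows, columns=["group", "accordance", "sd_a", "sd_b", "sd_diff"])
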