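"""Spatial variability statistics.

Per-field LAI aggregates, crop-abundance-weighted overall means and SDs via
the law of total variance (pooled variance), relative frequency
distributions (RFDs) with a fixed class width anchored at zero, the
histogram-overlap accordance statistic

    a = sum_c min(D_a,c, D_b,c)

(the fraction of values falling in the same class; equals 1 minus the
total-variation distance), and a normal-distribution comparator RFD built
from a mean and SD on the same class grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fields import FieldMap
from .raster import Raster, require_congruent

DEFAULT_CLASS_WIDTH = 0.1  # LAI units

__all__ = [
    "RFD",
    "CropStats",
    "field_aggregates",
    "overall_stats",
    "build_rfd",
    "weighted_rfd",
    "accordance",
    "normal_reference_rfd",
    "DEFAULT_CLASS_WIDTH",
]


@dataclass(frozen=True)
class RFD:
    """Relative frequency distribution with bins [c*w, (c+1)*w) anchored at 0.

    ``frequencies[c]`` is the relative frequency of class ``c``; classes run
    from 0 to the highest occupied class.  Frequencies are >= 0 and sum to 1.
    """

    class_width: float
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        if self.class_width <= 0:
            raise ValueError("class width must be positive")
        if np.any(self.frequencies < -1e-12):
            raise ValueError("frequencies must be non-negative")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @property
    def bin_lower_edges(self) -> np.ndarray:
        return np.arange(len(self.frequencies)) * self.class_width

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_lower": self.bin_lower_edges, "frequency": self.frequencies}
        )


def _pad_common(a: RFD, b: RFD) -> tuple[np.ndarray, np.ndarray]:
    if not np.isclose(a.class_width, b.class_width):
        raise ValueError(
            f"incompatible class widths {a.class_width} vs {b.class_width}"
        )
    n = max(len(a.frequencies), len(b.frequencies))
    fa = np.zeros(n)
    fb = np.zeros(n)
    fa[: len(a.frequencies)] = a.frequencies
    fb[: len(b.frequencies)] = b.frequencies
    return fa, fb


def build_rfd(values: np.ndarray, class_width: float = DEFAULT_CLASS_WIDTH) -> RFD:
    """Histogram of non-negative values on the zero-anchored class grid.

    Half-open bins: a value exactly on an edge goes to the upper class.
    """
    values = np.asarray(values, float).ravel()
    if values.size == 0:
        raise ValueError("cannot build an RFD from no values")
    if class_width <= 0:
        raise ValueError("class width must be positive")
    if np.any(values < 0):
        raise ValueError("RFD values must be >= 0")
    idx = np.floor(values / class_width + 1e-12).astype(np.int64)
    counts = np.bincount(idx)
    return RFD(class_width, counts / counts.sum())


def weighted_rfd(rfds: list[RFD], weights: np.ndarray) -> RFD:
    """Binwise convex combination of RFDs with abundance weights."""
    weights = np.asarray(weights, float)
    if len(rfds) != len(weights):
        raise ValueError("need one weight per RFD")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    weights = weights / weights.sum()
    n = max(len(r.frequencies) for r in rfds)
    w0 = rfds[0].class_width
    out = np.zeros(n)
    for r, w in zip(rfds, weights):
        if not np.isclose(r.class_width, w0):
            raise ValueError("all RFDs must share the class width")
        out[: len(r.frequencies)] += w * r.frequencies
    return RFD(w0, out)


def accordance(a: RFD, b: RFD) -> float:
    """Histogram overlap sum_c min(D_a,c, D_b,c) in [0, 1]."""
    fa, fb = _pad_common(a, b)
    return float(np.minimum(fa, fb).sum())


def normal_reference_rfd(
    mean: float, sd: float, class_width: float = DEFAULT_CLASS_WIDTH
) -> RFD:
    """RFD of a normal distribution discretized on the zero-anchored grid.

    Mass below zero is folded into the first class (empirical LAI cannot be
    negative); the tail above mean + 8 sd is folded into the last class and
    the result renormalized.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    upper = mean + 8 * sd
    n_bins = max(int(np.ceil(upper / class_width)), 1)
    edges = np.arange(n_bins + 1) * class_width
    cdf = sps.norm.cdf(edges, loc=mean, scale=sd)
    freqs = np.diff(cdf)
    freqs[0] += cdf[0]  # fold negative mass into the first class
    freqs[-1] += 1.0 - cdf[-1]
    return RFD(class_width, freqs / freqs.sum())


def field_aggregates(lai: Raster, fm: FieldMap) -> pd.DataFrame:
    """Per-field mean, population SD and valid-pixel count of LAI.

    Fields whose pixels are all nodata get ``missing = True`` with NaN
    statistics (absence, not zero).
    """
    require_congruent(lai, fm.labels)
    labels = fm.labels.data
    valid = lai.valid_mask() & (labels > 0)
    ids = fm.records["id"].to_numpy()
    if valid.any():
        lab_v = labels[valid]
        val_v = lai.data[valid]
        max_id = int(labels.max())
        n = np.bincount(lab_v, minlength=max_id + 1)
        s = np.bincount(lab_v, weights=val_v, minlength=max_id + 1)
        s2 = np.bincount(lab_v, weights=val_v**2, minlength=max_id + 1)
    else:
        max_id = int(ids.max()) if len(ids) else 0
        n = np.zeros(max_id + 1, dtype=np.int64)
        s = np.zeros(max_id + 1)
        s2 = np.zeros(max_id + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        var = np.maximum(s2 / n - mean**2, 0.0)
    out = pd.DataFrame(
        {
            "id": ids,
            "code": fm.records["code"].to_numpy(),
            "n": n[ids],
            "mean": mean[ids],
            "sd": np.sqrt(var[ids]),
            "missing": n[ids] == 0,
        }
    )
    out.loc[out["missing"], ["mean", "sd"]] = np.nan
    return out


@dataclass
class CropStats:
    """Per-crop LAI statistics with abundance weights.

    ``weights`` are the crop fractions of arable area from the original
    land-use classification (before mixed-pixel removal changed the
    relative abundances); they must sum to 1 over the analyzed crops plus
    any remainder already folded in.
    """

    crops: list[str]
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        self.counts = np.asarray(self.counts)
        self.weights = np.asarray(self.weights, float)
        if np.any(self.sds < 0) or np.any(self.weights < 0):
            raise ValueError("SDs and weights must be >= 0")


def overall_stats(
    stats: CropStats, include_between: bool = True
) -> tuple[float, float]:
    """Abundance-weighted overall mean and SD via pooled variance.

    With ``include_between`` (default) the pooled variance is the law of
    total variance, sum_i w_i (SD_i^2 + (mean_i - overall mean)^2); without
    it only the within-crop variances are pooled.  Weights must sum to 1.
    """
    w = stats.weights
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    mean = float(np.sum(w * stats.means))
    var = float(np.sum(w * stats.sds**2))
    if include_between:
        var += float(np.sum(w * (stats.means - mean) ** 2))
    return mean, float(np.sqrt(var))
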