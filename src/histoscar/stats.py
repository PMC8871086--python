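"""Per-ROI percentage metrics and group comparisons.

Each analyzed ROI is reduced to four percentages:

* ``fs_pct``  — foreground pixels (nuclei/glands/follicles) as % of all ROI pixels,
* ``cas_pct`` — collagen-cluster pixels as % of all ROI pixels,
* ``cdm_pct`` — mean of the collagen density map × 100,
* ``dv_pct``  — mean directional variance over valid pixels × 100
  (NaN when no pixel has a defined variance).

Groups of ROI metrics are compared with the pooled-variance (Student's)
two-sample t-test for two groups and one-way ANOVA otherwise; Welch's
unequal-variance t is available behind a flag.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError, DimensionError, ParameterError
from .fibers import VarianceMap
from .segmentation import SegmentationResult

__all__ = [
    "RoiMetrics",
    "GroupComparison",
    "summarize_roi",
    "student_t",
    "one_way_anova",
    "compare_regions",
    "metrics_to_frame",
]

METRIC_NAMES = ("fs_pct", "cas_pct", "cdm_pct", "dv_pct")


@dataclass
class RoiMetrics:
    fs_pct: float
    cas_pct: float
    cdm_pct: float
    dv_pct: float  # NaN when no valid DV pixel exists
    n_pixels: int
    n_valid_dv: int
    roi_id: str = ""
    group: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroupComparison:
    group_names: list[str]
    means: list[float]
    sds: list[float]
    statistic: float
    p_value: float
    test: str  # "student_t", "welch_t", or "one_way_anova"
    metric: str = ""

    def report(self) -> str:
        lines = [f"metric: {self.metric or '(values)'}  test: {self.test}"]
        for name, mean, sd in zip(self.group_names, self.means, self.sds):
            lines.append(f"  {name}: {mean:.3f} ± {sd:.3f}")
        stat_name = "F" if self.test == "one_way_anova" else "t"
        lines.append(f"  {stat_name} = {self.statistic:.4f}, p = {self.p_value:.4g}")
        return "\n".join(lines)


def summarize_roi(
    seg: SegmentationResult,
    density: np.ndarray,
    variance: VarianceMap,
    roi_id: str = "",
    group: str = "",
) -> RoiMetrics:
    """Reduce one ROI's masks and maps to the four percentage metrics."""
    density = np.asarray(density, dtype=np.float64)
    if not (seg.cas.shape == density.shape == variance.v.shape):
        raise DimensionError(
            f"frames differ: seg {seg.cas.shape}, density {density.shape}, "
            f"variance {variance.v.shape}"
        )
    n = seg.cas.size
    n_valid = int(np.count_nonzero(variance.valid))
    dv_pct = 100.0 * float(variance.v[variance.valid].mean()) if n_valid else math.nan
    return RoiMetrics(
        fs_pct=100.0 * np.count_nonzero(seg.fs) / n,
        cas_pct=100.0 * np.count_nonzero(seg.cas) / n,
        cdm_pct=100.0 * float(density.mean()),
        dv_pct=dv_pct,
        n_pixels=n,
        n_valid_dv=n_valid,
        roi_id=roi_id,
        group=group,
    )


def _validate_group(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ParameterError(f"group {name!r} needs >= 2 observations, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ParameterError(f"group {name!r} contains non-finite values")
    return arr


def student_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
    names: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided two-sample t-test, pooled-variance by default (Welch optional).

    Zero pooled variance with equal means follows the p = 1 convention; with
    unequal means it raises :class:`DegenerateVarianceError`.
    """
    a = _validate_group(group_a, names[0])
    b = _validate_group(group_b, names[1])
    pooled_var = ((a.var(ddof=1) * (a.size - 1)) + (b.var(ddof=1) * (b.size - 1))) / (
        a.size + b.size - 2
    )
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            raise DegenerateVarianceError(
                f"zero pooled variance with unequal means ({a.mean()} vs {b.mean()})"
            )
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group_names=list(names),
        means=[float(a.mean()), float(b.mean())],
        sds=[float(a.std(ddof=1)), float(b.std(ddof=1))],
        statistic=float(stat),
        p_value=float(p),
        test="welch_t" if welch else "student_t",
    )


def one_way_anova(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> GroupComparison:
    """One-way ANOVA: F = MS_between / MS_within with the standard decomposition.

    All-zero within-group variance follows the p = 1 convention when every
    group mean is equal, and raises otherwise.
    """
    if len(groups) < 2:
        raise ParameterError(f"ANOVA needs >= 2 groups, got {len(groups)}")
    names = list(names) if names is not None else [f"group{i}" for i in range(len(groups))]
    arrs = [_validate_group(g, n) for g, n in zip(groups, names)]
    within_ss = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    means = [float(a.mean()) for a in arrs]
    if within_ss == 0.0:
        if len(set(means)) == 1:
            stat, p = 0.0, 1.0
        else:
            raise DegenerateVarianceError(
                f"zero within-group variance with unequal means {means}"
            )
    else:
        stat, p = sps.f_oneway(*arrs)
    return GroupComparison(
        group_names=names,
        means=means,
        sds=[float(a.std(ddof=1)) for a in arrs],
        statistic=float(stat),
        p_value=float(p),
        test="one_way_anova",
    )


def compare_regions(
    metrics_by_group: dict[str, Sequence[RoiMetrics]],
    metric: str,
    welch: bool = False,
) -> GroupComparison:
    """Compare one metric across groups of ROIs.

    Dispatches to the Student's t-test for exactly two groups and to one-way
    ANOVA otherwise; reports mean ± sd per group.  NaN metric values
    (undefined DV) are excluded per group.
    """
    if metric not in METRIC_NAMES:
        raise ParameterError(f"unknown metric {metric!r}; valid: {METRIC_NAMES}")
    if len(metrics_by_group) < 2:
        raise ParameterError(f"need >= 2 groups, got {len(metrics_by_group)}")
    names = list(metrics_by_group)
    values = []
    for name in names:
        vals = [getattr(m, metric) for m in metrics_by_group[name]]
        vals = [v for v in vals if not math.isnan(v)]
        values.append(vals)
    if len(names) == 2:
        out = student_t(values[0], values[1], welch=welch, names=(names[0], names[1]))
    else:
        out = one_way_anova(values, names=names)
    out.metric = metric
    return out


def metrics_to_frame(metrics: Sequence[RoiMetrics]) -> pd.DataFrame:
    """Tabulate ROI metrics in the standard column order for CSV export."""
    cols = ["roi_id", "group", "fs_pct", "cas_pct", "cdm_pct", "dv_pct", "n_pixels", "n_valid_dv"]
    return pd.DataFrame([m.as_dict() for m in metrics])[cols]
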