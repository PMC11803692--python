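"""Region-of-interest summaries and the study's longitudinal statistics.

Quantitative maps are reduced to arithmetic means over labeled regions and
collected into a tidy table of (subject, group, week, region, metric,
value) records. Comparisons mirror the study's analysis plan: two-sided
paired t-tests between time points within a group, and two-sided unpaired
t-tests between groups on absolute values or on per-subject deltas between
successive time points. Results are reported as mean +/- SEM per arm with
t, degrees of freedom and p. No multiple-testing correction is applied by
default (the analysis is explicitly exploratory); a Benjamini-Hochberg
helper is provided for reuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "summarize_regions",
    "paired_timepoint_test",
    "longitudinal_deltas",
    "group_comparison_test",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["subject", "group", "week", "region", "metric", "value"]


@dataclass
class ComparisonResult:
    kind: str  # paired_timepoints | unpaired_groups | unpaired_delta
    metric: str
    region: str
    estimate: float  # mean difference (arm 1 minus arm 2 / week_b minus week_a)
    arm_means: tuple[float, float]
    arm_sems: tuple[float, float]
    arm_ns: tuple[int, int]
    t: float
    df: float
    p: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def summarize_regions(
    maps: dict[str, np.ndarray],
    labels: np.ndarray,
    region_ids: dict[str, int],
    subject: str,
    week: int,
    group: str,
    voxel_volume_mm3: float | None = None,
    validity: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Mean of each named map over each named region, as tidy table rows.

    ``maps`` maps metric name -> volume; ``validity`` (optional, same keys)
    restricts the mean to valid voxels. When ``voxel_volume_mm3`` is given
    a ``volume_mm3`` record (mask voxel count times voxel volume) is added
    per region. Regions with no valid voxels for a metric are skipped with
    a logged reason.
    """
    rows = []
    for region, rid in region_ids.items():
        mask = labels == rid
        if not mask.any():
            logger.info("region %s empty on this grid; skipped", region)
            continue
        if voxel_volume_mm3 is not None:
            rows.append(dict(subject=subject, group=group, week=week,
                             region=region, metric="volume_mm3",
                             value=float(mask.sum()) * voxel_volume_mm3))
        for metric, vol in maps.items():
            if vol.shape != mask.shape:
                raise ValueError(f"map '{metric}' does not share the mask grid")
            m = mask
            if validity and metric in validity:
                m = mask & validity[metric]
            if not m.any():
                logger.warning(
                    "region %s has no valid voxels for %s; omitted", region, metric
                )
                continue
            rows.append(dict(subject=subject, group=group, week=week,
                             region=region, metric=metric,
                             value=float(vol[m].mean())))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _pivot_pair(table: pd.DataFrame, group: str, region: str, metric: str,
                week_a: int, week_b: int) -> pd.DataFrame:
    sub = table[(table.group == group) & (table.region == region)
                & (table.metric == metric) & (table.week.isin([week_a, week_b]))]
    wide = sub.pivot_table(index="subject", columns="week", values="value")
    if week_a not in wide.columns or week_b not in wide.columns:
        return pd.DataFrame(columns=[week_a, week_b])
    if week_a == week_b:
        return wide[[week_a]].dropna()
    return wide[[week_a, week_b]].dropna()


def paired_timepoint_test(
    table: pd.DataFrame, group: str, region: str, metric: str,
    week_a: int, week_b: int,
) -> ComparisonResult:
    """Two-sided paired t-test between two imaging weeks within one group.

    Only subjects measured at both weeks enter; mean +/- SEM per week is
    reported over that paired subset.
    """
    wide = _pivot_pair(table, group, region, metric, week_a, week_b)
    if len(wide) < 2:
        raise ValueError(
            f"paired test needs >= 2 subjects with both weeks, got {len(wide)}"
        )
    a = wide[week_a].to_numpy()
    b = wide[week_b].to_numpy()
    diffs = b - a
    if np.allclose(diffs.std(ddof=1), 0.0) and np.allclose(diffs.mean(), 0.0):
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(b, a)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        kind="paired_timepoints", metric=metric, region=region,
        estimate=float(diffs.mean()),
        arm_means=(float(b.mean()), float(a.mean())),
        arm_sems=(_sem(b), _sem(a)),
        arm_ns=(len(b), len(a)),
        t=t_stat, df=float(len(diffs) - 1), p=p,
        label=f"{group} {region} {metric} wk{week_b} vs wk{week_a}",
    )


def longitudinal_deltas(table: pd.DataFrame, week_a: int, week_b: int) -> pd.DataFrame:
    """Per-subject differences value(week_b) - value(week_a).

    Returned as tidy rows with metric renamed to ``{metric}_delta`` and week
    set to week_b. Subjects missing either week are excluded (logged).
    """
    out_rows = []
    for (group, region, metric), _ in table.groupby(["group", "region", "metric"]):
        wide = _pivot_pair(table, group, region, metric, week_a, week_b)
        sub = table[(table.group == group) & (table.region == region)
                    & (table.metric == metric)]
        n_all = sub.subject.nunique()
        if len(wide) < n_all:
            logger.info("%s/%s/%s: %d of %d subjects lack a week and were "
                        "excluded from deltas", group, region, metric,
                        n_all - len(wide), n_all)
        for subject, row in wide.iterrows():
            out_rows.append(dict(subject=subject, group=group, week=week_b,
                                 region=region, metric=f"{metric}_delta",
                                 value=float(row[week_b] - row[week_a])))
    if not out_rows:
        logger.warning("no subjects share weeks %s and %s; empty delta table",
                       week_a, week_b)
    return pd.DataFrame(out_rows, columns=TABLE_COLUMNS)


def group_comparison_test(
    table: pd.DataFrame, group_1: str, group_2: str, region: str, metric: str,
    week: int | None = None, delta_weeks: tuple[int, int] | None = None,
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided unpaired t-test between groups.

    Compares absolute values at ``week`` or, when ``delta_weeks=(a, b)`` is
    given, the per-subject deltas between those weeks. The pooled-variance
    Student test is the default; set ``welch=True`` for unequal variances.
    """
    if (week is None) == (delta_weeks is None):
        raise ValueError("specify exactly one of week or delta_weeks")
    if delta_weeks is not None:
        dt = longitudinal_deltas(table, *delta_weeks)
        sub = dt[(dt.region == region) & (dt.metric == f"{metric}_delta")]
        kind = "unpaired_delta"
    else:
        sub = table[(table.region == region) & (table.metric == metric)
                    & (table.week == week)]
        kind = "unpaired_groups"
    x1 = sub[sub.group == group_1].value.to_numpy()
    x2 = sub[sub.group == group_2].value.to_numpy()
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("unpaired test needs >= 2 subjects per group")
    if np.allclose(x1.std(ddof=1), 0) and np.allclose(x2.std(ddof=1), 0) \
            and np.allclose(x1.mean(), x2.mean()):
        t_stat, p, df = 0.0, 1.0, float(len(x1) + len(x2) - 2)
        logger.warning("degenerate variance in both arms with equal means; p=1")
    else:
        res = stats.ttest_ind(x1, x2, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return ComparisonResult(
        kind=kind, metric=metric, region=region,
        estimate=float(x1.mean() - x2.mean()),
        arm_means=(float(x1.mean()), float(x2.mean())),
        arm_sems=(_sem(x1), _sem(x2)),
        arm_ns=(len(x1), len(x2)),
        t=t_stat, df=df, p=p,
        label=f"{group_1} vs {group_2} {region} {metric} "
              + (f"wk{week}" if week is not None else f"d{delta_weeks}"),
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (optional; the default analysis is uncorrected)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return out
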