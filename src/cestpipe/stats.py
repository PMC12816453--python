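"""ROI aggregation, IQR outlier exclusion and group comparison.

Subject-level analysis works on ROI means of the parametric maps.  Within
each group (per metric) subjects are screened once by the Tukey fence rule:
x is an outlier iff x > Q3 + 1.5*IQR or x < Q1 - 1.5*IQR, quartiles by
linear interpolation between order statistics (the convention is exposed
because exclusion counts depend on it).

Group comparison follows a normality-gated decision tree: Shapiro-Wilk per
group at alpha = 0.05; if every group passes, one-way ANOVA with Tukey HSD
pairwise comparisons; otherwise Kruskal-Wallis with pairwise Wilcoxon
rank-sum tests corrected by Benjamini-Hochberg.  The report records which
branch fired, the global and pairwise p-values, and significance stars at
0.05 / 0.01.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import EmptyROIError, InsufficientDataError
from .metrics import ParametricMap

__all__ = [
    "CohortTable",
    "GroupComparisonReport",
    "roi_mean",
    "exclude_outliers",
    "compare_groups",
]

COHORT_COLUMNS = ["subject_id", "group", "metric_name", "value",
                  "included", "exclusion_reason"]


def roi_mean(pmap: ParametricMap, roi: np.ndarray) -> tuple[float, int]:
    """Arithmetic mean of the metric over valid ROI voxels, with the count."""
    vals = pmap.roi_values(roi)
    return float(vals.mean()), int(vals.size)


def quartiles(values: np.ndarray, convention: str = "linear") -> tuple[float, float]:
    """(Q1, Q3) under the configured quantile convention."""
    return (float(np.percentile(values, 25, method=convention)),
            float(np.percentile(values, 75, method=convention)))


def exclude_outliers(values, convention: str = "linear",
                     min_n: int = 4) -> np.ndarray:
    """Tukey-fence inclusion indicator for one group's values.

    Applied once (not iterated).  Groups smaller than ``min_n`` are left
    untouched — the rule is skipped, everything included.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_n:
        return np.ones(v.shape, dtype=bool)
    q1, q3 = quartiles(v, convention)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (v >= lo) & (v <= hi)


@dataclass
class CohortTable:
    """Per-subject ROI-mean metric values with group labels.

    One row per subject x metric; ``included`` / ``exclusion_reason`` are
    filled by :meth:`apply_outlier_exclusion`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("subject_id", "group", "metric_name", "value")
                   if c not in self.data.columns]
        if missing:
            raise InsufficientDataError(f"cohort table missing columns {missing}")
        self.data = self.data.copy()
        if "included" not in self.data.columns:
            self.data["included"] = True
        if "exclusion_reason" not in self.data.columns:
            self.data["exclusion_reason"] = ""
        dup = self.data.duplicated(subset=["subject_id", "metric_name"])
        if dup.any():
            raise InsufficientDataError("duplicate subject x metric rows")

    def apply_outlier_exclusion(self, convention: str = "linear") -> "CohortTable":
        """Per-group, per-metric IQR fence exclusion on subject ROI means."""
        df = self.data.copy()
        for (_, _), idx in df.groupby(["group", "metric_name"]).groups.items():
            sub = df.loc[idx]
            keep = exclude_outliers(sub["value"].to_numpy(), convention)
            df.loc[idx, "included"] = keep
            df.loc[idx[~keep], "exclusion_reason"] = "iqr_fence"
        return CohortTable(df)

    def included_values(self, metric: str) -> dict[str, np.ndarray]:
        df = self.data
        sel = (df["metric_name"] == metric) & df["included"]
        return {g: grp["value"].to_numpy()
                for g, grp in df[sel].groupby("group", sort=True)}


@dataclass
class GroupComparisonReport:
    """Outcome of the normality-gated comparison for one metric."""

    metric_name: str
    branch: str                      # "anova_tukey" | "kruskal_bh" | "degenerate"
    shapiro_p: dict
    global_p: float
    pairwise_p: dict
    stars: dict = field(default_factory=dict)
    group_summary: dict = field(default_factory=dict)

    def significant_pairs(self, alpha: float = 0.05) -> list:
        return [pair for pair, p in self.pairwise_p.items()
                if np.isfinite(p) and p < alpha]


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(table: CohortTable, metric: str, alpha: float = 0.05,
                   min_group_n: int = 3) -> GroupComparisonReport:
    """Run the decision tree on one metric's included subject values.

    Raises :class:`InsufficientDataError` unless at least two groups have
    ``min_group_n`` included values.  Zero within-group variance everywhere
    short-circuits to the ``degenerate`` branch with no tests run.
    """
    groups = table.included_values(metric)
    groups = {g: v for g, v in groups.items() if v.size >= min_group_n}
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >= 2 groups with >= {min_group_n} values for {metric!r}")
    names = sorted(groups)
    values = [groups[g] for g in names]
    summary = {g: {"n": int(v.size), "mean": float(v.mean()),
                   "sd": float(v.std(ddof=1))} for g, v in groups.items()}

    if all(np.ptp(v) == 0 for v in values):
        return GroupComparisonReport(
            metric_name=metric, branch="degenerate", shapiro_p={},
            global_p=float("nan"), pairwise_p={}, group_summary=summary)

    shapiro_p = {}
    for g, v in groups.items():
        # Shapiro-Wilk is undefined for a constant sample; a constant group
        # is maximally non-normal for our purposes
        shapiro_p[g] = float(sps.shapiro(v).pvalue) if np.ptp(v) > 0 else 0.0
    normal = all(p > alpha for p in shapiro_p.values())

    pairs = list(itertools.combinations(names, 2))
    if normal:
        branch = "anova_tukey"
        global_p = float(sps.f_oneway(*values).pvalue)
        tk = sps.tukey_hsd(*values)
        pairwise = {(names[i], names[j]): float(tk.pvalue[i, j]) for i, j in
                    itertools.combinations(range(len(names)), 2)}
    else:
        branch = "kruskal_bh"
        global_p = float(sps.kruskal(*values).pvalue)
        raw = [float(sps.ranksums(groups[a], groups[b]).pvalue) for a, b in pairs]
        adj = multipletests(raw, alpha=alpha, method="fdr_bh")[1]
        pairwise = dict(zip(pairs, (float(p) for p in adj)))

    return GroupComparisonReport(
        metric_name=metric, branch=branch, shapiro_p=shapiro_p,
        global_p=global_p, pairwise_p=pairwise,
        stars={pair: _stars(p) for pair, p in pairwise.items()},
        group_summary=summary)
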