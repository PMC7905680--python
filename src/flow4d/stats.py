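"""Group-comparison procedure for cohort biomarker tables.

Per metric: a Shapiro-Wilk normality gate on every group at alpha = 0.05
routes the comparison either to one-way ANOVA with Tukey's honestly
significant difference post hoc (parametric) or to Kruskal-Wallis with
Bonferroni-corrected pairwise rank tests (nonparametric).  Groups smaller
than 3 cannot be tested for normality and force the nonparametric route.
Summaries are mean +/- sample SD (n-1 denominator).

The nonparametric post hoc defaults to pairwise Mann-Whitney U tests with
Bonferroni correction over the contrasts; Dunn's rank-sum z test is
available via ``posthoc="dunn"``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    p_adjusted: float
    statistic: float


@dataclass
class StatsResult:
    metric: str
    route: str  # "parametric" | "nonparametric"
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: List[PairwiseComparison]
    group_summary: pd.DataFrame  # group, n, mean, sd
    degenerate: bool = False

    def significant_pairs(self, alpha: float = 0.05) -> List[Tuple[str, str]]:
        return [(c.group_a, c.group_b) for c in self.pairwise if c.p_adjusted < alpha]


def normality_gate(groups: Sequence[np.ndarray], alpha: float = 0.05) -> str:
    """Route selection: parametric iff every group passes Shapiro-Wilk.

    Any group with fewer than 3 observations forces the nonparametric
    route (the test is undefined there).
    """
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 3:
            warnings.warn(
                "group with n < 3: normality untestable, using nonparametric route",
                stacklevel=2,
            )
            return "nonparametric"
        if np.ptp(g) == 0:
            return "nonparametric"  # Shapiro-Wilk undefined for constant data
        if sps.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def _dunn_pairwise(groups: Dict[str, np.ndarray]) -> List[PairwiseComparison]:
    """Dunn's z test on pooled ranks with tie correction, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    out = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(PairwiseComparison(a, b, min(1.0, p * n_pairs), float(z)))
    return out


def _mannwhitney_pairwise(groups: Dict[str, np.ndarray]) -> List[PairwiseComparison]:
    names = list(groups)
    n_pairs = len(names) * (len(names) - 1) // 2
    out = []
    for a, b in itertools.combinations(names, 2):
        res = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        out.append(PairwiseComparison(a, b, min(1.0, res.pvalue * n_pairs), float(res.statistic)))
    return out


def summarize(
    table: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group mean +/- sample SD (ddof=1) per metric; SD empty for n=1."""
    if metrics is None:
        metrics = [
            c
            for c in table.columns
            if c not in (group_col, "subject_id") and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for metric in metrics:
        for g, sub in table.groupby(group_col, sort=False):
            vals = sub[metric].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "metric": metric,
                    "group": g,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def group_compare(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    alpha: float = 0.05,
    posthoc: str = "mannwhitney",
    route: Optional[str] = None,
) -> StatsResult:
    """Omnibus + post-hoc comparison of one metric across all groups.

    The route is chosen by the normality gate unless forced via ``route``.
    All pairwise contrasts are always reported with adjusted p-values.
    A metric constant across all subjects is degenerate and reported as
    p = 1 with a flag.
    """
    groups: Dict[str, np.ndarray] = {}
    for g, sub in table.groupby(group_col, sort=False):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations for {metric!r}")
        groups[str(g)] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")

    summary = summarize(table, [metric], group_col)
    names = list(groups)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        pairwise = [PairwiseComparison(a, b, 1.0, 0.0) for a, b in itertools.combinations(names, 2)]
        return StatsResult(metric, "degenerate", "none", 0.0, 1.0, pairwise, summary, True)

    chosen = route or normality_gate(list(groups.values()), alpha)
    if chosen == "parametric":
        omni = sps.f_oneway(*groups.values())
        tukey = sps.tukey_hsd(*groups.values())
        pairwise = [
            PairwiseComparison(
                names[i], names[j], float(tukey.pvalue[i, j]), float(tukey.statistic[i, j])
            )
            for i, j in itertools.combinations(range(len(names)), 2)
        ]
        return StatsResult(
            metric, "parametric", "anova", float(omni.statistic), float(omni.pvalue),
            pairwise, summary,
        )
    omni = sps.kruskal(*groups.values())
    if posthoc == "dunn":
        pairwise = _dunn_pairwise(groups)
    elif posthoc == "mannwhitney":
        pairwise = _mannwhitney_pairwise(groups)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}; use 'mannwhitney' or 'dunn'")
    return StatsResult(
        metric, "nonparametric", "kruskal", float(omni.statistic), float(omni.pvalue),
        pairwise, summary,
    )


def compare_all(
    table: pd.DataFrame,
    metrics: Sequence[str],
    group_col: str = "group",
    alpha: float = 0.05,
    posthoc: str = "mannwhitney",
) -> pd.DataFrame:
    """Tidy table of omnibus and pairwise results for several metrics."""
    rows = []
    for metric in metrics:
        res = group_compare(table, metric, group_col, alpha, posthoc)
        for c in res.pairwise:
            rows.append(
                {
                    "metric": metric,
                    "route": res.route,
                    "omnibus_test": res.omnibus_test,
                    "omnibus_p": res.omnibus_p,
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.p_adjusted < alpha,
                }
            )
    return pd.DataFrame(rows)
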