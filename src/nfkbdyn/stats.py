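"""Group summaries and nonparametric genotype comparisons.

Metrics are compared across genotypes with the Kruskal-Wallis rank test
(tie-corrected) followed by Dunn's pairwise post-hoc z tests with a
Bonferroni-style multiplicity adjustment over all unordered pairs — the
procedure GraphPad Prism applies as "Dunn's multiple comparison test".
A Holm step-down adjustment is available as an alternative. Cells lacking
a metric (e.g. no second peak) are excluded from that metric's moments but
counted in the denominator of the fraction-with-metric statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .metrics import CellMetrics, metrics_table


@dataclass
class GroupSummary:
    genotype: str
    metric: str
    n: int  # cells with the metric defined
    n_total: int  # all cells in the group
    mean: float
    sd: float
    median: float
    min: float
    max: float
    fraction_with_metric: float  # percent of group with the metric defined


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class ComparisonResult:
    metric: str
    h_statistic: float
    kw_p: float
    pairwise: dict[tuple[str, str], PairwiseResult] = field(default_factory=dict)


def summarize_group(
    metrics: list[CellMetrics] | pd.DataFrame, metric: str, genotype: str | None = None
) -> GroupSummary:
    """Summary statistics of one metric in one genotype group.

    ``metrics`` may be CellMetrics objects or a metrics table. NaN values
    mark cells lacking the metric; they are dropped from the moment
    statistics but kept in the fraction denominator.
    """
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_table(metrics)
    if genotype is not None:
        df = df[df["genotype"] == genotype]
    if metric not in df.columns:
        raise KeyError(f"unknown metric {metric!r}")
    values = df[metric].to_numpy(dtype=float)
    n_total = len(values)
    if n_total < 1:
        raise ValueError("need at least one cell")
    defined = values[~np.isnan(values)]
    n = defined.size
    gt = genotype if genotype is not None else (
        df["genotype"].iloc[0] if df["genotype"].nunique() == 1 else "all"
    )
    if n == 0:
        return GroupSummary(gt, metric, 0, n_total, np.nan, np.nan, np.nan,
                            np.nan, np.nan, 0.0)
    return GroupSummary(
        genotype=gt,
        metric=metric,
        n=n,
        n_total=n_total,
        mean=float(defined.mean()),
        sd=float(defined.std(ddof=1)) if n > 1 else 0.0,
        median=float(np.median(defined)),
        min=float(defined.min()),
        max=float(defined.max()),
        fraction_with_metric=100.0 * n / n_total,
    )


def kruskal_wallis_dunn(
    groups: dict[str, np.ndarray | list[float]],
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    metric: str = "",
) -> ComparisonResult:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post-hoc tests.

    H is computed on pooled mid-ranks with the standard tie correction;
    Dunn z uses mean-rank differences with the tie-corrected pooled
    variance, and two-sided p values are adjusted over all unordered
    pairs (Bonferroni by default, Holm optionally). All-identical data
    give H = 0, p = 1. Deterministic; rank-based, so invariant under any
    strictly monotone transform of the values.
    """
    if adjust not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 1:
            raise ValueError(f"group {k!r} is empty")
        if np.isnan(v).any():
            data[k] = v[~np.isnan(v)]
            if data[k].size < 1:
                raise ValueError(f"group {k!r} has no defined values")
    pooled = np.concatenate([data[k] for k in names])
    sizes = np.array([data[k].size for k in names])
    n_tot = pooled.size
    ranks = rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(names))]
    )

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    tie_factor = 1.0 - tie_sum / (n_tot**3 - n_tot) if n_tot > 1 else 0.0

    rank_sums = mean_ranks * sizes
    h_raw = 12.0 / (n_tot * (n_tot + 1)) * np.sum(rank_sums**2 / sizes) - 3 * (n_tot + 1)
    if tie_factor <= 0:  # every value identical
        result = ComparisonResult(metric=metric, h_statistic=0.0, kw_p=1.0)
        for a, b in combinations(names, 2):
            result.pairwise[(a, b)] = PairwiseResult((a, b), 0.0, 1.0, 1.0)
        return result
    h = h_raw / tie_factor
    kw_p = float(chi2.sf(h, df=len(names) - 1))

    sigma2_base = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    pairs = list(combinations(range(len(names)), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(sigma2_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * norm.sf(abs(z)))
    m = len(pairs)
    if adjust == "bonferroni":
        p_adj = [min(1.0, p * m) for p in ps]
    else:  # holm step-down
        order = np.argsort(ps)
        p_adj_arr = np.empty(m)
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, min(1.0, (m - rank) * ps[k]))
            p_adj_arr[k] = running
        p_adj = list(p_adj_arr)

    result = ComparisonResult(metric=metric, h_statistic=float(h), kw_p=kw_p)
    for (i, j), z, p, pa in zip(pairs, zs, ps, p_adj):
        key = (names[i], names[j])
        result.pairwise[key] = PairwiseResult(key, float(z), float(p), float(pa))
    return result


def significance_stars(p: float) -> str:
    """Prism-style significance marks: *** <0.0001, ** <0.01, * <0.05."""
    if p < 0.0001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summary_table(
    metrics_df: pd.DataFrame, metric_names: list[str] | None = None
) -> pd.DataFrame:
    """Summary CSV body: one row per (genotype, metric)."""
    if metric_names is None:
        metric_names = [
            c for c in metrics_df.columns if c not in ("cell_id", "genotype")
        ]
    rows = []
    for gt in sorted(metrics_df["genotype"].unique()):
        for m in metric_names:
            s = summarize_group(metrics_df, m, genotype=gt)
            rows.append(
                {
                    "genotype": gt,
                    "metric": m,
                    "n": s.n,
                    "n_total": s.n_total,
                    "mean": s.mean,
                    "sd": s.sd,
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                    "pct_with_metric": s.fraction_with_metric,
                }
            )
    return pd.DataFrame(rows)


def comparison_table(
    metrics_df: pd.DataFrame,
    metric_names: list[str] | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Comparisons CSV body: one row per (metric, genotype pair)."""
    if metric_names is None:
        metric_names = [
            c for c in metrics_df.columns if c not in ("cell_id", "genotype")
        ]
    rows = []
    for m in metric_names:
        groups = {}
        for gt in sorted(metrics_df["genotype"].unique()):
            vals = metrics_df.loc[metrics_df["genotype"] == gt, m].dropna().to_numpy()
            if vals.size:
                groups[gt] = vals
        if len(groups) < 2:
            continue
        res = kruskal_wallis_dunn(groups, adjust=adjust, metric=m)
        for (a, b), pw in res.pairwise.items():
            rows.append(
                {
                    "metric": m,
                    "group_a": a,
                    "group_b": b,
                    "H": res.h_statistic,
                    "kw_p": res.kw_p,
                    "dunn_z": pw.z,
                    "p_unadjusted": pw.p_unadjusted,
                    "p_adjusted": pw.p_adjusted,
                    "stars": significance_stars(pw.p_adjusted),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["metric", "group_a", "group_b", "H", "kw_p", "dunn_z",
                 "p_unadjusted", "p_adjusted", "stars"],
    )
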