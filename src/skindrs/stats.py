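"""Descriptive summaries and nonparametric group comparisons.

Skin optical properties are skewed across subjects, so summaries use medians
with interquartile ranges (linear-interpolation quantiles between order
statistics).  Group comparisons follow the cohort-study recipe: Mann-Whitney
U for two groups, Kruskal-Wallis for three or more, Dunn's rank-based post
hoc z-tests with Bonferroni multiplication for pairwise follow-up, and an
ordinary least-squares regression for the age trend of the scattering
amplitude.  p < 0.05 is flagged as significant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "summarize",
    "group_tests",
    "dunn_posthoc",
    "trend_regression",
    "GroupTestReport",
    "TrendResult",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


def summarize(values: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Median and 25th/75th percentiles of each numeric column.

    Quantiles use linear interpolation between order statistics.  With
    ``by``, one summary row is produced per (group, quantity) pair.
    """
    if len(values) < 1:
        raise ValueError("at least one observation is required")

    def _one(df: pd.DataFrame) -> pd.DataFrame:
        num = df.select_dtypes("number")
        rows = []
        for col in num.columns:
            v = num[col].dropna().to_numpy()
            if v.size == 0:
                continue
            p25, med, p75 = np.quantile(v, [0.25, 0.5, 0.75])
            rows.append({"quantity": col, "median": med, "p25": p25, "p75": p75, "n": v.size})
        return pd.DataFrame(rows)

    if by is None:
        return _one(values)
    out = []
    for key, df in values.groupby(by, observed=True):
        t = _one(df.drop(columns=[by]))
        t.insert(0, by, key)
        out.append(t)
    return pd.concat(out, ignore_index=True)


@dataclass
class GroupTestReport:
    test: str                  # "mann-whitney" or "kruskal-wallis"
    statistic: float
    p_value: float
    significant: bool
    groups: list
    posthoc: pd.DataFrame | None = None


def _check_groups(groups: dict) -> dict:
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    clean = {}
    for k, v in groups.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise ValueError(f"group {k!r} has fewer than two observations")
        clean[k] = arr
    return clean


def group_tests(values, groups=None) -> GroupTestReport:
    """Compare a quantity between groups.

    ``values`` and ``groups`` are equal-length sequences (observation and its
    group label), or ``values`` may be a mapping label -> observations with
    ``groups=None``.  Two groups: Mann-Whitney U (exact for small untied
    samples, otherwise normal approximation with tie correction).  Three or
    more: Kruskal-Wallis, followed by Dunn's Bonferroni-corrected post hoc.
    """
    if isinstance(values, dict):
        data = _check_groups(values)
    elif groups is None:
        raise ValueError("groups labels are required unless values is a mapping")
    else:
        v = np.asarray(values, dtype=float)
        g = np.asarray(groups)
        data = _check_groups({k: v[g == k] for k in pd.unique(g)})
    labels = list(data)
    if len(labels) == 2:
        res = sps.mannwhitneyu(data[labels[0]], data[labels[1]], alternative="two-sided")
        return GroupTestReport(
            test="mann-whitney",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            significant=res.pvalue < SIGNIFICANCE_LEVEL,
            groups=labels,
        )
    res = sps.kruskal(*[data[k] for k in labels])
    posthoc = dunn_posthoc(data)
    return GroupTestReport(
        test="kruskal-wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=res.pvalue < SIGNIFICANCE_LEVEL,
        groups=labels,
        posthoc=posthoc,
    )


def dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Dunn's pairwise rank z-tests with Bonferroni-multiplied p-values.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); p-values are multiplied by
    the number of comparisons and capped at 1.
    """
    data = _check_groups(groups)
    labels = list(data)
    pooled = np.concatenate([data[k] for k in labels])
    ranks = sps.rankdata(pooled)
    N = pooled.size
    idx = 0
    mean_ranks = {}
    for k in labels:
        n_k = data[k].size
        mean_ranks[k] = ranks[idx: idx + n_k].mean()
        idx += n_k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / data[a].size + 1.0 / data[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_adjusted": p,
                "significant": p < SIGNIFICANCE_LEVEL,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrendResult:
    slope: float
    intercept: float
    stderr: float
    p_value: float
    n: int


def trend_regression(x, y) -> TrendResult:
    """Ordinary least-squares regression of ``y`` on ``x`` (e.g. alpha on age)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        stderr=float(model.bse[1]),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
    )
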