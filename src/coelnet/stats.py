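"""Trend and group-comparison statistics for sweep results.

Thin, validated wrappers around the standard implementations: Spearman
rank correlation for feature-count trends, the Brunner-Munzel rank test
(t approximation) for two-group comparisons, Fisher's method for P-value
aggregation, the two-proportion z test, and Bonferroni adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "spearman_trend",
    "brunner_munzel",
    "fishers_method",
    "proportion_test",
    "bonferroni",
]


def spearman_trend(result: pd.DataFrame, metric: str) -> tuple[float, float]:
    """Spearman correlation between feature count and a sweep metric.

    ``result`` must carry an ``n_features`` column and the metric column;
    rows with an undefined metric are ignored.  Requires at least 3
    defined rows; returns ``(nan, nan)`` when the metric (or the feature
    count) has zero variance.
    """
    df = result[["n_features", metric]].dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 defined rows for {metric!r}, got {len(df)}")
    x = df["n_features"].to_numpy(dtype=float)
    y = df[metric].to_numpy(dtype=float)
    if np.all(y == y[0]) or np.all(x == x[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def brunner_munzel(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Brunner-Munzel test with t-approximation P-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Brunner-Munzel needs >= 2 observations per sample")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        raise ValueError("degenerate variance: all observations identical")
    res = sps.brunnermunzel(a, b, alternative="two-sided", distribution="t")
    return float(res.statistic), float(res.pvalue)


def fishers_method(p_values) -> tuple[float, float]:
    """Combine independent P-values: chi2 = -2 sum(ln p) on 2k df."""
    ps = np.asarray(list(p_values), dtype=float)
    if len(ps) == 0:
        raise ValueError("no P-values to combine")
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("P-values must lie in (0, 1]")
    stat, p = sps.combine_pvalues(ps, method="fisher")
    return float(stat), float(p)


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided two-proportion z test (no continuity correction)."""
    if min(n1, n2) <= 0:
        raise ValueError("sample sizes must be positive")
    _, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(p)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni family-wise adjustment, capped at 1."""
    ps = np.asarray(list(p_values), dtype=float)
    return np.minimum(ps * len(ps), 1.0)
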