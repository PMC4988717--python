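"""Baseline-comparison statistics for the two-period tables.

2x2 chi-square is uncorrected Pearson (identical to the squared pooled
two-proportion z statistic); Fisher's exact test is two-sided by the
point-probability method; continuous comparisons use the Mann-Whitney
rank-sum test (exact for combined n <= 12 without ties) or Welch's t.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    return arr


def expected_counts(table) -> np.ndarray:
    arr = _as_2x2(table)
    total = arr.sum()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total


def chi_square_2x2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table, 1 df."""
    arr = _as_2x2(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a zero margin")
    if np.any(expected_counts(arr) < 5):
        warnings.warn("expected cell count < 5; consider Fisher's exact test")
    a, b = arr[0]
    c, d = arr[1]
    n = arr.sum()
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables with the observed margins whose point probability does not
    exceed the observed one."""
    arr = _as_2x2(table).astype(int)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Mann-Whitney U: exact enumeration when the combined sample size is
    at most 12 and tie-free, otherwise the tie-corrected normal
    approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    small = x.size + y.size <= 12 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if small else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def welch_mean_diff(x, y) -> tuple[float, tuple[float, float], float]:
    """Mean difference x - y with Welch-Satterthwaite 95% CI and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(0.95)
    return (
        float(x.mean() - y.mean()),
        (float(ci.low), float(ci.high)),
        float(res.pvalue),
    )


def choose_2x2_test(table) -> tuple[str, float]:
    """Advisory selection rule: chi-square when all expected counts are at
    least 5, Fisher's exact otherwise. Returns (test name, p)."""
    arr = _as_2x2(table)
    if np.all(expected_counts(arr) >= 5):
        return "chi_square", chi_square_2x2(arr)[1]
    return "fisher_exact", fisher_exact_2x2(arr)


def table_one(
    df: pd.DataFrame,
    variables: list[tuple[str, str]],
    group_col: str = "period",
) -> pd.DataFrame:
    """Two-group baseline table: for each (column, kind) with kind
    ``binary`` report counts/percent per group and a 2x2 test, for kind
    ``continuous`` report median (IQR) per group and the rank-sum p."""
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"{group_col!r} must have exactly two levels, got {groups}")
    g0 = df[df[group_col] == groups[0]]
    g1 = df[df[group_col] == groups[1]]
    rows = []
    for col, kind in variables:
        if kind == "binary":
            a, b = int(g0[col].sum()), len(g0) - int(g0[col].sum())
            c, d = int(g1[col].sum()), len(g1) - int(g1[col].sum())
            test, p = choose_2x2_test([[a, b], [c, d]])
            rows.append(
                {
                    "variable": col,
                    f"{groups[0]}_n": a,
                    f"{groups[0]}_pct": 100.0 * a / max(len(g0), 1),
                    f"{groups[1]}_n": c,
                    f"{groups[1]}_pct": 100.0 * c / max(len(g1), 1),
                    "test": test,
                    "p_value": p,
                }
            )
        elif kind == "continuous":
            x = g0[col].dropna().to_numpy()
            y = g1[col].dropna().to_numpy()
            _, p = rank_sum_test(x, y)
            rows.append(
                {
                    "variable": col,
                    f"{groups[0]}_median": float(np.median(x)),
                    f"{groups[0]}_iqr": f"{np.percentile(x, 25):.1f}-{np.percentile(x, 75):.1f}",
                    f"{groups[1]}_median": float(np.median(y)),
                    f"{groups[1]}_iqr": f"{np.percentile(y, 25):.1f}-{np.percentile(y, 75):.1f}",
                    "test": "rank_sum",
                    "p_value": p,
                }
            )
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {col!r}")
    return pd.DataFrame(rows)
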