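"""Monthly aggregation and segmented (interrupted time series) regression.

The study calendar has 24 analysed months: 12 pre-program (indices 1..12)
and 12 program months (13..24); the initiation month sits between them and
is excluded. The segmented model is ordinary least squares on

    Y_t = b0 + b1 * t + b2 * post_t + b3 * (t - t0) * post_t + e_t

with post_t = 1 for t >= 13 and t0 = 12, so b0 is the starting level, b1
the baseline trend per month, b2 the change in level at the intervention
and b3 the change in trend. Proportions are modelled untransformed, one
point per month, and the Durbin-Watson statistic diagnoses first-order
autocorrelation of the residuals (no correction is applied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson

from .domain import INITIATION_MONTH

#: ordered study months -> 1..24 (initiation month absent)
def study_month_index(initiation: tuple[int, int] = INITIATION_MONTH) -> dict[str, int]:
    year, month = initiation
    months: list[str] = []
    y, m = year - 1, month  # twelve months before the initiation month
    for _ in range(12):
        months.append(f"{y:04d}-{m:02d}")
        m += 1
        if m > 12:
            y, m = y + 1, 1
    m += 1  # skip the initiation month itself
    if m > 12:
        y, m = y + 1, 1
    for _ in range(12):
        months.append(f"{y:04d}-{m:02d}")
        m += 1
        if m > 12:
            y, m = y + 1, 1
    return {label: i + 1 for i, label in enumerate(months)}


OUTCOME_COLUMNS = {
    "effective": ("eff_time", "eff_event", None),
    "optimal": ("opt_time", "opt_event", None),
    "deescalation": ("deesc_time", "deesc_event", "deesc_eligible"),
    "ivpo": ("ivpo_time", "ivpo_event", None),
}


def monthly_series(
    outcome_table: pd.DataFrame,
    landmark_h: float,
    event: str,
    initiation: tuple[int, int] = INITIATION_MONTH,
) -> pd.DataFrame:
    """Per calendar month, the proportion of eligible episodes with the
    event by the landmark hour. Months without eligible episodes are kept
    with an absent proportion and flagged."""
    if event not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {event!r}")
    t_col, e_col, elig_col = OUTCOME_COLUMNS[event]
    df = outcome_table
    if elig_col is not None:
        df = df[df[elig_col]]
    index = study_month_index(initiation)
    rows = []
    for month, idx in index.items():
        sub = df[df["month"] == month]
        n = len(sub)
        if n == 0:
            rows.append({"month": month, "month_index": idx, "proportion": np.nan, "n_episodes": 0, "empty": True})
        else:
            hit = ((sub[e_col]) & (sub[t_col] <= landmark_h)).sum()
            rows.append(
                {
                    "month": month,
                    "month_index": idx,
                    "proportion": hit / n,
                    "n_episodes": n,
                    "empty": False,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SegmentedFit:
    """Wagner-style segmented OLS fit: level, baseline trend, change in
    level, change in trend, their standard errors and p-values (t tests on
    n - 4 df), and the Durbin-Watson statistic of the residuals."""

    params: np.ndarray  # (b0, b1, b2, b3)
    bse: np.ndarray
    pvalues: np.ndarray
    durbin_watson: float
    residuals: np.ndarray
    nobs: int
    t0: float

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta1(self) -> float:
        return float(self.params[1])

    @property
    def beta2(self) -> float:
        return float(self.params[2])

    @property
    def beta3(self) -> float:
        return float(self.params[3])

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        post = (t > self.t0).astype(float)
        return self.params[0] + self.params[1] * t + self.params[2] * post + self.params[3] * (t - self.t0) * post


def fit_segmented(series: pd.DataFrame, t0: float = 12.0) -> SegmentedFit:
    """OLS fit of the segmented model to a monthly series (columns
    ``month_index`` and ``proportion``; absent months are dropped)."""
    data = series.dropna(subset=["proportion"])
    t = data["month_index"].to_numpy(dtype=float)
    y = data["proportion"].to_numpy(dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 monthly points")
    post = (t > t0).astype(float)
    if post.min() == post.max():
        raise ValueError("all points on one side of the intervention: collinear design")
    if (post == 0).sum() < 2 or (post == 1).sum() < 2:
        raise ValueError("need at least 2 points on each side of the intervention")
    X = np.column_stack([np.ones_like(t), t, post, (t - t0) * post])
    fit = sm.OLS(y, X).fit()
    resid = np.asarray(fit.resid)
    # an (effectively) perfect fit leaves no residual signal: DW undefined
    degenerate = np.max(np.abs(resid)) <= 1e-10 * max(1.0, float(np.max(np.abs(y))))
    dw = float("nan") if degenerate else durbin_watson(resid)
    return SegmentedFit(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        pvalues=np.asarray(fit.pvalues),
        durbin_watson=dw,
        residuals=resid,
        nobs=int(fit.nobs),
        t0=t0,
    )


def durbin_watson(residuals) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2, in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    if not np.any(e != 0.0):
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_durbin_watson(e))


def its_report(
    outcome_table: pd.DataFrame,
    landmarks: tuple[float, ...] = (24.0, 48.0),
    outcomes: tuple[str, ...] = ("effective", "optimal", "deescalation", "ivpo"),
    t0: float = 12.0,
) -> pd.DataFrame:
    """Segmented-regression report: one row per outcome series (outcome x
    landmark hour) with the four coefficient/p pairs and the DW statistic."""
    rows = []
    for outcome in outcomes:
        for landmark in landmarks:
            series = monthly_series(outcome_table, landmark, outcome)
            fit = fit_segmented(series, t0=t0)
            rows.append(
                {
                    "outcome": outcome,
                    "landmark_h": landmark,
                    "intercept": fit.beta0,
                    "intercept_p": fit.pvalues[0],
                    "baseline_trend": fit.beta1,
                    "baseline_trend_p": fit.pvalues[1],
                    "level_change": fit.beta2,
                    "level_change_p": fit.pvalues[2],
                    "trend_change": fit.beta3,
                    "trend_change_p": fit.pvalues[3],
                    "durbin_watson": fit.durbin_watson,
                }
            )
    return pd.DataFrame(rows)
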