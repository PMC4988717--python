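"""Kaplan-Meier estimation and the two-group log-rank test.

The product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i) with
Greenwood's variance S(t)^2 * sum d_i / (n_i (n_i - d_i)) and the standard
tie convention (events processed before censorings at equal times).
Landmark proportions use the plain linear normal interval on 1 - S(t);
the median CI inverts the sign test on S(t) -/+ 1.96 se crossing 0.5.

Censoring policy (240 h horizon, death, discharge) is applied upstream by
the therapy classifier; inputs here are final (duration, event) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray  # S(t_i)
    greenwood_var: np.ndarray  # Var[S(t_i)]
    max_observed: float  # largest duration in the sample (event or censored)

    def survival_at(self, t: float) -> tuple[float, float]:
        """(S(t), Var S(t)) by right-continuous step lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0, 0.0
        return float(self.survival[idx]), float(self.greenwood_var[idx])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (time, at-risk, deaths, survival, variance) for
        plotting."""
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
            }
        )


def km_fit(durations, event_observed) -> KMCurve:
    """Product-limit estimate of the survivor function."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(event_observed, dtype=bool)
    if durations.size == 0:
        raise ValueError("empty sample")
    if durations.size != events.size:
        raise ValueError("durations and event indicators differ in length")
    if np.any(durations < 0):
        raise ValueError("negative durations")

    event_times, deaths = np.unique(durations[events], return_counts=True)
    sorted_durations = np.sort(durations)
    # risk set includes ties: events precede censorings at equal times
    at_risk = durations.size - np.searchsorted(sorted_durations, event_times, side="left")
    frac = 1.0 - deaths / at_risk
    survival = np.cumprod(frac)
    terms = np.where(
        at_risk > deaths,
        deaths / (at_risk * np.maximum(at_risk - deaths, 1).astype(float)),
        0.0,
    )
    greenwood = survival**2 * np.cumsum(terms)
    greenwood[survival == 0.0] = 0.0  # convention: degenerate tail has zero variance
    return KMCurve(
        times=event_times,
        at_risk=at_risk,
        deaths=deaths,
        survival=survival,
        greenwood_var=greenwood,
        max_observed=float(durations.max()),
    )


def km_proportion_at(curve: KMCurve, t: float) -> tuple[float, float, float, bool]:
    """Cumulative event proportion 1 - S(t) with a linear Greenwood 95% CI
    clipped to [0, 1]. The final flag marks extrapolation beyond the last
    observed duration (the last value is carried forward)."""
    if t < 0:
        raise ValueError("landmark time must be >= 0")
    extrapolated = t > curve.max_observed
    s, var = curve.survival_at(min(t, curve.max_observed) if extrapolated else t)
    p = 1.0 - s
    half = Z95 * np.sqrt(var)
    return p, max(0.0, p - half), min(1.0, p + half), extrapolated


def km_median(curve: KMCurve) -> tuple[float | None, tuple[float | None, float | None]]:
    """Smallest t with S(t) <= 0.5, absent when the curve never reaches 0.5.
    CI bounds from S(t) -/+ 1.96 se crossing 0.5 (sign-test inversion)."""
    se = np.sqrt(curve.greenwood_var)

    def first_crossing(values) -> float | None:
        hits = np.nonzero(values <= 0.5)[0]
        return float(curve.times[hits[0]]) if hits.size else None

    median = first_crossing(curve.survival)
    lower = first_crossing(curve.survival - Z95 * se)
    upper = first_crossing(curve.survival + Z95 * se)
    return median, (lower, upper)


def log_rank(
    durations_a, events_a, durations_b, events_b
) -> tuple[float, float]:
    """Standard two-group log-rank test: chi-square (1 df) from the summed
    observed-minus-expected events with hypergeometric variance at each
    distinct event time."""
    da = np.asarray(durations_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    db = np.asarray(durations_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if da.size == 0 or db.size == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([da[ea], db[eb]])
    if pooled.size == 0:
        warnings.warn("no events in either group; log-rank p-value set to 1")
        return 0.0, 1.0
    event_times = np.unique(pooled)

    # counting-process tallies per event time via sorted lookups
    def _tallies(dur, ev):
        at_risk = dur.size - np.searchsorted(np.sort(dur), event_times, side="left")
        t_ev, counts = np.unique(dur[ev], return_counts=True)
        deaths = np.zeros(event_times.size, dtype=np.int64)
        deaths[np.searchsorted(event_times, t_ev)] = counts
        return at_risk, deaths

    n_a, d_a = _tallies(da, ea)
    n_b, d_b = _tallies(db, eb)
    n = n_a + n_b
    d = d_a + d_b

    expected_a = d * n_a / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n > 1, d * (n_a / n) * (n_b / n) * (n - d) / (n - 1.0), 0.0
        )
    o_minus_e = float(np.sum(d_a - expected_a))
    v = float(np.sum(var))
    if v == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p
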