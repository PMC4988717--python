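"""Seeded generator of two-period synthetic BSI cohorts.

The generator draws per-episode ground truth first (period, calendar month,
pathogen, empirical-therapy category, event times, censoring) and then
constructs raw records — culture sets, AST panels, administration timelines
and admissions — that realize those truths exactly when run through the
pipeline. Event times are drawn directly per outcome from period-specific
exponential models (the analysis consumes times; a mechanistic prescribing
model would be invention), then snapped onto each administration record's
own dosing grid; the stored truth is recomputed from the realized record
times so the end-to-end identity holds with exact float equality.

Defaults emulate the published two-period cohort: 648/678 included episodes
over 12 + 12 study months, the Table 1 empirical-therapy mix (allocated by
largest-remainder quota so the pre-period counts are exactly 317 optimal /
181 superfluous / 21 other / 129 ineffective), Table 2 pathogen marginals,
and landmark calibrations such as effective therapy at 24 h ~= 87.8% pre
vs ~= 94.4% program. All of it is synthetic: labels, not measurements.

Injected exclusions (age, location, early death, discharge-before-report,
polymicrobial growth, initiation-month onset), contaminant-only and
SIRS-absent culture sets, repeat cultures inside an episode and
late-recurrence / different-infection separate episodes are labeled in a
side-channel truth table so selection accounting is testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .domain import (
    ABSENT,
    GRAM_NEGATIVE,
    IV,
    OPEN,
    PO,
    PROGRAM_START,
    STUDY_ORIGIN,
    Admission,
    AdministrationRecord,
    ASTResult,
    BloodCultureSet,
    KnowledgeBase,
    StepFlag,
    datetime_to_hours,
    month_of,
    snap_to_grid,
)

HORIZON_H = 240.0

CAT_INEFFECTIVE = "ineffective"
CAT_SUPERFLUOUS = "effective_superfluous"
CAT_OTHER = "effective_other_nonoptimal"
CAT_OPTIMAL = "optimal"
CATEGORIES = (CAT_OPTIMAL, CAT_SUPERFLUOUS, CAT_OTHER, CAT_INEFFECTIVE)

_DOSE_H = 8.0  # q8h dosing grid for every IV order


def _month_starts(first_year: int, first_month: int, count: int) -> list[tuple[str, float, float]]:
    """(label, start hour, duration hours) for consecutive calendar months."""
    from datetime import datetime

    out = []
    y, m = first_year, first_month
    for _ in range(count):
        start = datetime(y, m, 1)
        ny, nm = (y + 1, 1) if m == 12 else (y, m + 1)
        end = datetime(ny, nm, 1)
        out.append(
            (
                f"{y:04d}-{m:02d}",
                datetime_to_hours(start, STUDY_ORIGIN),
                (end - start).total_seconds() / 3600.0,
            )
        )
        y, m = ny, nm
    return out


PRE_MONTHS = _month_starts(2010, 8, 12)  # Aug 2010 .. Jul 2011
INITIATION = _month_starts(2011, 8, 1)[0]  # Aug 2011, excluded
POST_MONTHS = _month_starts(2011, 9, 12)  # Sep 2011 .. Aug 2012


def _rate_from_landmark(p: float, t: float = 24.0) -> float:
    """Exponential rate with P(T <= t) = p."""
    return -math.log1p(-p) / t


@dataclass
class PeriodParams:
    """Study conditions of one period. Rates are per hour."""

    n_episodes: int
    empirical_mix: tuple[float, float, float, float]  # optimal, superfluous, other, ineffective
    pathogen_mix: dict[str, float]
    esbl_frac: float
    mrsa_frac: float
    icu_frac: float
    acquisition_mix: tuple[float, float, float]  # community, healthcare, hospital
    report_delay_range: tuple[float, float]
    effective_rate: float  # time to effective therapy, ineffective-empirical episodes
    deescalation_rate: float  # superfluous-empirical episodes
    other_optimal_rate: float  # dose-correction among "other non-optimal" episodes
    switch_prob: float  # IV-to-oral switch among episodes reaching optimal therapy
    switch_rate: float
    death30_frac: float
    infection_related_frac: float  # among 30-day deaths
    los_median_days: float
    consult_cancel_frac: float
    prior_consult_frac_canceled: float
    prior_consult_frac_other: float


_PATHOGEN_PRE = {
    "Escherichia coli": 0.378,
    "Klebsiella pneumoniae": 0.137,
    "Pseudomonas aeruginosa": 0.039,
    "Enterobacter cloacae": 0.032,
    "Proteus mirabilis": 0.011,
    "Acinetobacter baumannii": 0.008,
    "Staphylococcus aureus": 0.139,
    "Coagulase-negative staphylococci": 0.025,
    "Streptococcus species": 0.071,
    "Enterococcus faecalis": 0.057,
    "Bacteroides fragilis": 0.025,
    "Candida albicans": 0.040,
}

_PATHOGEN_POST = {
    "Escherichia coli": 0.317,
    "Klebsiella pneumoniae": 0.171,
    "Pseudomonas aeruginosa": 0.056,
    "Enterobacter cloacae": 0.022,
    "Proteus mirabilis": 0.006,
    "Acinetobacter baumannii": 0.012,
    "Staphylococcus aureus": 0.134,
    "Coagulase-negative staphylococci": 0.050,
    "Streptococcus species": 0.056,
    "Enterococcus faecalis": 0.061,
    "Bacteroides fragilis": 0.028,
    "Candida albicans": 0.028,
}


def default_pre_params() -> PeriodParams:
    return PeriodParams(
        n_episodes=648,
        empirical_mix=(317 / 648, 181 / 648, 21 / 648, 129 / 648),
        pathogen_mix=_PATHOGEN_PRE,
        esbl_frac=0.322,
        mrsa_frac=0.522,
        icu_frac=0.071,
        acquisition_mix=(0.292, 0.298, 0.410),
        report_delay_range=(48.0, 90.0),
        effective_rate=_rate_from_landmark(0.388),
        deescalation_rate=_rate_from_landmark(0.282),
        other_optimal_rate=_rate_from_landmark(0.45),
        switch_prob=0.304,
        switch_rate=0.00684,
        death30_frac=68 / 648,
        infection_related_frac=39 / 68,
        los_median_days=16.6,
        consult_cancel_frac=0.0,
        prior_consult_frac_canceled=0.45,
        prior_consult_frac_other=0.45,
    )


def default_post_params() -> PeriodParams:
    return PeriodParams(
        n_episodes=678,
        empirical_mix=(337 / 678, 170 / 678, 20 / 678, 151 / 678),
        pathogen_mix=_PATHOGEN_POST,
        esbl_frac=0.442,
        mrsa_frac=0.516,
        icu_frac=0.117,
        acquisition_mix=(0.282, 0.320, 0.398),
        report_delay_range=(39.0, 81.0),
        effective_rate=_rate_from_landmark(0.748),
        deescalation_rate=_rate_from_landmark(0.571),
        other_optimal_rate=_rate_from_landmark(0.70),
        switch_prob=0.343,
        switch_rate=0.00641,
        death30_frac=67 / 678,
        infection_related_frac=27 / 67,
        los_median_days=16.0,
        consult_cancel_frac=0.22,
        prior_consult_frac_canceled=0.51,
        prior_consult_frac_other=0.45,
    )


@dataclass
class InjectionCounts:
    """Per-period counts of injected non-included material."""

    age_under_18: int = 4
    not_hospitalized: int = 4
    discharged_before_report: int = 6
    polymicrobial: int = 6
    early_death: int = 6
    contaminant_sets: int = 10
    sirs_absent_sets: int = 3
    repeat_cultures: int = 4
    recurrence_pairs: int = 3  # new episode >= 2 weeks after a host episode
    different_infection_pairs: int = 2  # flagged separate episode within 2 weeks


@dataclass
class CohortSpec:
    """Full specification of a synthetic two-period cohort."""

    pre: PeriodParams = field(default_factory=default_pre_params)
    post: PeriodParams = field(default_factory=default_post_params)
    injections: InjectionCounts = field(default_factory=InjectionCounts)
    initiation_month_episodes: int = 8
    inappropriate_switch_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for params in (self.pre, self.post):
            if abs(sum(params.empirical_mix) - 1.0) > 1e-9:
                raise ValueError("empirical_mix must sum to 1")
            if min(
                params.effective_rate, params.deescalation_rate, params.other_optimal_rate
            ) <= 0:
                raise ValueError("event-time rates must be > 0")


@dataclass
class CohortData:
    cultures: list[BloodCultureSet]
    asts: list[ASTResult]
    admissions: dict[str, Admission]
    administrations: list[AdministrationRecord]
    kb: KnowledgeBase
    truth: pd.DataFrame
    noise_sets: pd.DataFrame  # contaminant-only / SIRS-absent sets (never episodes)


def largest_remainder(probs, n: int) -> list[int]:
    """Deterministic integer allocation of n items to len(probs) cells."""
    probs = np.asarray(probs, dtype=float)
    raw = probs * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(short):
        base[order[i]] += 1
    return base.tolist()


# --------------------------------------------------------------------------
# Agent scenarios per pathogen


def _scenario(pathogen: str, esbl: bool, mrsa: bool, category: str) -> dict:
    """Agents and susceptibility panel realizing a category for a pathogen.

    Returns codes for the ineffective empirical agent (X), the narrow active
    agent (N), the broad superfluous agent (B, absent where no superfluous
    list applies) and the oral agent (PO, absent when no active oral form
    exists), plus the S/I/R panel.
    """
    if pathogen in (
        "Escherichia coli",
        "Klebsiella pneumoniae",
        "Pseudomonas aeruginosa",
        "Enterobacter cloacae",
        "Proteus mirabilis",
        "Acinetobacter baumannii",
    ):
        if esbl:
            if category == CAT_SUPERFLUOUS:
                panel = {"CRO": "R", "CFZ": "R", "CAZ": "R", "FEP": "R", "TZP": "R",
                         "MEM": "S", "IPM": "S", "CIP": "S", "CIP-PO": "S", "GEN": "R"}
                return {"X": "CRO", "N": "CIP", "B": "MEM", "PO": "CIP-PO", "panel": panel}
            panel = {"CRO": "R", "CFZ": "R", "CAZ": "R", "FEP": "R", "TZP": "R",
                     "MEM": "S", "IPM": "S", "CIP": "R", "CIP-PO": "R", "GEN": "R"}
            return {"X": "CRO", "N": "MEM", "B": None, "PO": None, "panel": panel}
        panel = {"CRO": "S", "CFZ": "R", "MEM": "S", "TZP": "S", "CIP": "S",
                 "CIP-PO": "S", "GEN": "S"}
        return {"X": "CFZ", "N": "CRO", "B": "MEM", "PO": "CIP-PO", "panel": panel}

    if pathogen in ("Staphylococcus aureus", "Coagulase-negative staphylococci"):
        if mrsa:
            panel = {"CFZ": "R", "NAF": "R", "AMP": "R", "VAN": "S", "TEC": "S",
                     "LZD": "S", "LZD-PO": "S", "GEN": "R"}
            return {"X": "NAF", "N": "VAN", "B": None, "PO": "LZD-PO", "panel": panel}
        panel = {"CFZ": "S", "NAF": "S", "AMP": "R", "VAN": "S", "LEX-PO": "S", "GEN": "R"}
        return {"X": "AMP", "N": "CFZ", "B": "VAN", "PO": "LEX-PO", "panel": panel}

    if pathogen in ("Streptococcus species", "Enterococcus faecalis", "Corynebacterium species"):
        panel = {"AMP": "S", "AMX-PO": "S", "VAN": "S", "GEN": "R", "CFZ": "I"}
        return {"X": "GEN", "N": "AMP", "B": "VAN", "PO": "AMX-PO", "panel": panel}

    if pathogen == "Bacteroides fragilis":
        panel = {"MTZ": "S", "MTZ-PO": "S", "CFZ": "R"}
        return {"X": "CFZ", "N": "MTZ", "B": None, "PO": "MTZ-PO", "panel": panel}

    if pathogen == "Candida albicans":
        panel = {"FLU": "S", "FLU-PO": "S", "CAS": "S", "CFZ": "R"}
        return {"X": "CFZ", "N": "FLU", "B": None, "PO": "FLU-PO", "panel": panel}

    raise ValueError(f"no scenario for pathogen {pathogen!r}")


def _superfluous_capable(pathogen: str, esbl: bool) -> bool:
    """Whether a superfluous-broad-spectrum empirical regimen can be
    realized for this pathogen (a designated broad agent plus a susceptible
    non-superfluous alternative must exist)."""
    return _scenario(pathogen, esbl, False, CAT_SUPERFLUOUS).get("B") is not None


# --------------------------------------------------------------------------
# Record-building helpers


def _grid_stop_record(
    patient_id: str, agent: str, stop_abs: float, ref: float, dose_ok: bool = True
) -> AdministrationRecord:
    """IV order running before the reference time and discontinued exactly at
    ``stop_abs``: doses q8h, last given dose one interval before the stop,
    start at least 6 h before the reference."""
    k = max(1, math.ceil((stop_abs - ref + 6.0) / _DOSE_H))
    start = stop_abs - _DOSE_H * k
    doses = [start + _DOSE_H * i for i in range(k)]
    return AdministrationRecord(
        patient_id=patient_id,
        agent_code=agent,
        route=IV,
        start_at=start,
        stop_at=stop_abs,
        scheduled_times=doses,
        dose_adequate=dose_ok,
    )


def _open_record(
    patient_id: str,
    agent: str,
    start_abs: float,
    sched_until: float,
    dose_ok: bool = True,
    route: str = IV,
) -> AdministrationRecord:
    n = max(1, int((sched_until - start_abs) // _DOSE_H) + 1)
    doses = [start_abs + _DOSE_H * i for i in range(n)]
    return AdministrationRecord(
        patient_id=patient_id,
        agent_code=agent,
        route=route,
        start_at=start_abs,
        stop_at=OPEN,
        scheduled_times=doses,
        dose_adequate=dose_ok,
    )


def _close_record_at(record: AdministrationRecord, at_or_after: float) -> None:
    """Stop an open order at its first dose slot >= the given time."""
    start = record.start_at
    k = max(1, math.ceil((at_or_after - start) / _DOSE_H))
    stop = start + _DOSE_H * k
    record.scheduled_times = [t for t in record.scheduled_times if t <= stop - _DOSE_H]
    if not record.scheduled_times:
        record.scheduled_times = [start]
    record.stop_at = record.scheduled_times[-1] + _DOSE_H


def _truth_censor(ref: float, death_at: float, discharged_at: float, horizon: float = HORIZON_H):
    """Censoring time/reason with the pipeline's float expressions and tie
    precedence (death > discharge > horizon)."""
    c_death = death_at - ref if not math.isnan(death_at) else math.inf
    c_disc = discharged_at - ref if not math.isinf(discharged_at) else math.inf
    c = min(horizon, c_death, c_disc)
    if c_death == c:
        return c, "death"
    if c_disc == c:
        return c, "discharge"
    return c, "horizon_240h"


# --------------------------------------------------------------------------
# Generator


class _Counter:
    def __init__(self):
        self.patient = 0
        self.set = 0
        self.isolate = 0

    def next_patient(self) -> str:
        self.patient += 1
        return f"P{self.patient:05d}"

    def next_set(self) -> str:
        self.set += 1
        return f"BC{self.set:06d}"

    def next_isolate(self) -> str:
        self.isolate += 1
        return f"ISO{self.isolate:06d}"


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate the full record set plus the ground-truth table.

    Deterministic given ``spec.seed``: the RNG is a single
    ``numpy.random.default_rng`` stream consumed in a fixed order (pre-period
    months, post-period months, then injections).
    """
    rng = np.random.default_rng(spec.seed)
    ids = _Counter()
    cultures: list[BloodCultureSet] = []
    asts: list[ASTResult] = []
    admissions: dict[str, Admission] = {}
    admins: list[AdministrationRecord] = []
    truth_rows: list[dict] = []
    noise_rows: list[dict] = []

    for period_name, params, months in (
        ("pre_program", spec.pre, PRE_MONTHS),
        ("program", spec.post, POST_MONTHS),
    ):
        _generate_period(
            spec, rng, ids, period_name, params, months,
            cultures, asts, admissions, admins, truth_rows,
        )
        _generate_period_injections(
            spec, rng, ids, period_name, params, months,
            cultures, asts, admissions, admins, truth_rows, noise_rows,
        )
    _generate_initiation_month(
        spec, rng, ids, cultures, asts, admissions, admins, truth_rows
    )

    truth = pd.DataFrame(truth_rows)
    noise = pd.DataFrame(
        noise_rows, columns=["set_id", "patient_id", "kind", "organism"]
    )
    return CohortData(
        cultures=cultures,
        asts=asts,
        admissions=admissions,
        administrations=admins,
        kb=KnowledgeBase(),
        truth=truth,
        noise_sets=noise,
    )


def generate_truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Ground-truth outcomes consistent with ``generate_cohort`` under the
    same seed (same draw stream)."""
    return generate_cohort(spec).truth


def _generate_period(
    spec, rng, ids, period_name, params, months,
    cultures, asts, admissions, admins, truth_rows,
):
    inj = spec.injections

    # deterministic category quota over the whole period, shuffled; the
    # different-infection episodes ride on a host's running therapy and are
    # therefore empirically optimal, so they must consume optimal slots
    counts = largest_remainder(params.empirical_mix, params.n_episodes)
    categories = [c for c, k in zip(CATEGORIES, counts) for _ in range(k)]
    n_diff = min(inj.different_infection_pairs, counts[0])
    for _ in range(n_diff):
        categories.remove(CAT_OPTIMAL)
    n_recur = min(inj.recurrence_pairs, len(categories))
    rng.shuffle(categories)
    recur_categories = categories[:n_recur]
    ordinary_categories = categories[n_recur:]

    n_ordinary = len(ordinary_categories)
    month_alloc = largest_remainder([1 / 12.0] * 12, n_ordinary)

    ordinary_specs: list[dict] = []  # per-episode context for host selection
    cat_iter = iter(ordinary_categories)
    for (label, m0, dur), n_month in zip(months, month_alloc):
        for _ in range(n_month):
            category = next(cat_iter)
            ctx = _generate_episode(
                spec, rng, ids, period_name, params, label, m0, dur, category,
                cultures, asts, admissions, admins, truth_rows,
            )
            ordinary_specs.append(ctx)

    # special separate-episode constructs
    hosts = [
        c for c in ordinary_specs
        if c["month_pos"] <= 9
        and not c["has_death"]
        and not c["switched"]
        and c["horizon_censored"]  # discharge extension must not change censoring
    ]
    rng.shuffle(hosts)
    # commensal pathogens need the two-set rule, which the single flagged
    # culture of a different-infection episode would fail
    optimal_hosts = [
        h for h in hosts
        if h["category"] == CAT_OPTIMAL
        and h["pathogen"] != "Coagulase-negative staphylococci"
    ]
    other_hosts = [h for h in hosts if h["category"] != CAT_OPTIMAL]
    for category in recur_categories:
        host = (other_hosts or optimal_hosts).pop()
        _generate_recurrence(
            spec, rng, ids, period_name, params, host, category,
            cultures, asts, admissions, admins, truth_rows,
        )
    for _ in range(n_diff):
        host = optimal_hosts.pop()
        _generate_different_infection(
            spec, rng, ids, period_name, params, host,
            cultures, asts, admissions, admins, truth_rows,
        )


def _draw_admission_frame(rng, params, onset, ref):
    """Admission skeleton around an episode: acquisition type, admit/ED
    clocks, ICU and age."""
    acq = ("community", "healthcare_associated", "hospital_onset")[
        rng.choice(3, p=np.asarray(params.acquisition_mix) / sum(params.acquisition_mix))
    ]
    if acq == "hospital_onset":
        admitted = snap_to_grid(onset - rng.uniform(48.0, 500.0))
        ed = ABSENT
        exposure = bool(rng.random() < 0.5)
    else:
        admitted = snap_to_grid(onset - rng.uniform(0.0, 40.0))
        ed = admitted if rng.random() < 0.6 else ABSENT
        exposure = acq == "healthcare_associated"
    age = float(np.clip(rng.normal(66.0, 16.0), 18.0, 100.0))
    icu = bool(rng.random() < params.icu_frac)
    return acq, admitted, ed, exposure, round(age, 1), icu


def _generate_episode(
    spec, rng, ids, period_name, params, month_label, m0, dur, category,
    cultures, asts, admissions, admins, truth_rows,
    *, patient_id=None, onset=None, admission=None, month_pos=None,
):
    """One included episode with full records; returns a context dict used
    for host selection. When ``patient_id``/``admission`` are given the
    episode is attached to an existing patient (late recurrence)."""
    inj = spec.injections
    new_patient = patient_id is None
    if new_patient:
        patient_id = ids.next_patient()
        onset = snap_to_grid(m0 + rng.uniform(0.0, dur - 96.0))
    delay = rng.uniform(*params.report_delay_range)
    ref = snap_to_grid(onset + delay)

    # pathogen compatible with the category quota
    mix = params.pathogen_mix
    names = list(mix)
    probs = np.asarray([mix[n] for n in names], dtype=float)
    if category == CAT_SUPERFLUOUS:
        mask = np.asarray([_superfluous_capable(n, False) for n in names])
        probs = probs * mask
    probs = probs / probs.sum()
    pathogen = names[rng.choice(len(names), p=probs)]
    esbl = pathogen == "Escherichia coli" and bool(rng.random() < params.esbl_frac)
    mrsa = (
        pathogen == "Staphylococcus aureus"
        and category != CAT_SUPERFLUOUS
        and bool(rng.random() < params.mrsa_frac)
    )
    scen = _scenario(pathogen, esbl, mrsa, category)
    from .domain import gram_category as _gram

    gram = _gram(pathogen)

    # admission / outcome draws
    if new_patient:
        acq, admitted, ed, exposure, age, icu = _draw_admission_frame(rng, params, onset, ref)
        death = ABSENT
        ir_mech = ""
        if rng.random() < params.death30_frac:
            if rng.random() < params.infection_related_frac:
                ir_mech = ("flags", "two_week", "culture")[rng.choice(3, p=[0.5, 0.3, 0.2])]
            else:
                ir_mech = "none"
            if ir_mech == "two_week":
                death = snap_to_grid(ref + rng.uniform(25.0, 330.0))
            elif ir_mech == "culture":
                death = snap_to_grid(ref + rng.uniform(25.0, 200.0))
            else:
                death = snap_to_grid(ref + rng.uniform(25.0, 620.0))
        if math.isnan(death):
            los_h = 24.0 * float(rng.lognormal(math.log(params.los_median_days), 0.5))
            discharged = snap_to_grid(max(onset + los_h, ref + rng.uniform(24.0, 72.0)))
        else:
            discharged = death
    else:
        adm0 = admission
        acq, admitted, ed, exposure, age, icu = (
            "hospital_onset", adm0.admitted_at, adm0.ed_visit_at,
            adm0.healthcare_exposure, adm0.age_years, adm0.icu_at_onset,
        )
        death = ABSENT
        ir_mech = ""
        discharged = max(adm0.discharged_at, snap_to_grid(ref + 280.0))

    censor_t, censor_reason = _truth_censor(ref, death, discharged)
    timeline_end = snap_to_grid(min(discharged, ref + 260.0))

    # ------------------------------------------------------------------
    # therapy timeline realizing the category and drawn event times
    ep_admins: list[AdministrationRecord] = []
    t_eff = t_opt = t_deesc = None  # event offsets (None = no event realized)
    grid_anchor = None  # open IV record carrying the therapy at/after optimality

    if category == CAT_OPTIMAL:
        start0 = snap_to_grid(ref - rng.uniform(6.0, 48.0))
        rec = _open_record(patient_id, scen["N"], start0, timeline_end)
        ep_admins.append(rec)
        t_eff, t_opt = 0.0, 0.0
        grid_anchor = rec
    elif category == CAT_SUPERFLUOUS:
        t_d_abs = snap_to_grid(ref + rng.exponential(1.0 / params.deescalation_rate))
        if t_d_abs - ref <= censor_t:
            ep_admins.append(_grid_stop_record(patient_id, scen["B"], t_d_abs, ref))
            rec = _open_record(patient_id, scen["N"], t_d_abs, max(timeline_end, t_d_abs))
            ep_admins.append(rec)
            t_deesc = t_d_abs - ref
            t_opt = t_d_abs - ref
            grid_anchor = rec
        else:
            ep_admins.append(
                _open_record(patient_id, scen["B"], snap_to_grid(ref - rng.uniform(6.0, 48.0)), timeline_end)
            )
        t_eff = 0.0
    elif category == CAT_OTHER:
        start0 = snap_to_grid(ref - rng.uniform(6.0, 48.0))
        ep_admins.append(_open_record(patient_id, scen["N"], start0, timeline_end, dose_ok=False))
        t_o_abs = snap_to_grid(ref + rng.exponential(1.0 / params.other_optimal_rate))
        if t_o_abs - ref <= censor_t:
            rec = _open_record(patient_id, scen["N"], t_o_abs, max(timeline_end, t_o_abs))
            ep_admins.append(rec)
            t_opt = t_o_abs - ref
            grid_anchor = rec
        t_eff = 0.0
    else:  # ineffective empirical therapy
        t_e_abs = snap_to_grid(ref + rng.exponential(1.0 / params.effective_rate))
        if t_e_abs - ref <= censor_t:
            ep_admins.append(_grid_stop_record(patient_id, scen["X"], t_e_abs, ref))
            immediate = rng.random() < 0.5
            rec1 = _open_record(
                patient_id, scen["N"], t_e_abs, max(timeline_end, t_e_abs), dose_ok=immediate
            )
            ep_admins.append(rec1)
            t_eff = t_e_abs - ref
            if immediate:
                t_opt = t_e_abs - ref
                grid_anchor = rec1
            else:
                t_o_abs = snap_to_grid(t_e_abs + rng.exponential(12.0))
                if t_o_abs - ref <= censor_t:
                    rec2 = _open_record(patient_id, scen["N"], t_o_abs, max(timeline_end, t_o_abs))
                    ep_admins.append(rec2)
                    t_opt = t_o_abs - ref
                    grid_anchor = rec2
        else:
            ep_admins.append(
                _open_record(patient_id, scen["X"], snap_to_grid(ref - rng.uniform(6.0, 48.0)), timeline_end)
            )

    # ------------------------------------------------------------------
    # IV-to-oral switch
    t_ivpo = None
    inappropriate_switch = False
    switched = False
    flags = {
        "afebrile": StepFlag(snap_to_grid(ref + rng.uniform(24.0, 120.0))),
        "inflammatory_markers_decreasing": StepFlag(snap_to_grid(ref + rng.uniform(24.0, 120.0))),
        "symptoms_improving": StepFlag(snap_to_grid(ref + rng.uniform(24.0, 120.0))),
        "oral_intake_normal": StepFlag(
            snap_to_grid(ref + rng.uniform(24.0, 200.0)) if rng.random() < 0.5 else OPEN
        ),
    }
    iv_only = bool(rng.random() < 0.15)
    may_switch = (
        grid_anchor is not None
        and scen["PO"] is not None
        and rng.random() < params.switch_prob
    )
    if may_switch:
        anchor = grid_anchor.start_at
        floor_t = max(ref, anchor)
        raw = rng.exponential(1.0 / params.switch_rate)
        t_sw_abs = anchor + _DOSE_H * (math.floor((floor_t + raw - anchor) / _DOSE_H) + 1)
        if t_sw_abs - ref <= censor_t:
            switched = True
            inappropriate_switch = bool(rng.random() < spec.inappropriate_switch_frac)
            iv_only = False
            if inappropriate_switch:
                flags = {
                    "afebrile": StepFlag(snap_to_grid(t_sw_abs - rng.uniform(1.0, 12.0))),
                    "inflammatory_markers_decreasing": StepFlag(snap_to_grid(t_sw_abs - rng.uniform(1.0, 12.0))),
                    "symptoms_improving": StepFlag(snap_to_grid(t_sw_abs - rng.uniform(1.0, 12.0))),
                    "oral_intake_normal": StepFlag(OPEN),  # vomiting: criterion 5 fails
                }
            else:
                flags = {
                    name: StepFlag(snap_to_grid(t_sw_abs - rng.uniform(1.0, 12.0)))
                    for name in (
                        "afebrile",
                        "inflammatory_markers_decreasing",
                        "symptoms_improving",
                        "oral_intake_normal",
                    )
                }
                t_ivpo = t_sw_abs - ref
            for rec in ep_admins:
                if math.isinf(rec.stop_at) and rec.route == IV:
                    _close_record_at(rec, t_sw_abs)
            ep_admins.append(
                _open_record(
                    patient_id, scen["PO"], t_sw_abs,
                    max(timeline_end, t_sw_abs), route=PO,
                )
            )

    # ------------------------------------------------------------------
    # persistence: admission, culture set(s), AST, records
    set_id = ids.next_set()
    canceled = bool(
        period_name == "program" and rng.random() < params.consult_cancel_frac
    )
    prior = bool(
        rng.random()
        < (params.prior_consult_frac_canceled if canceled else params.prior_consult_frac_other)
    )
    commensal = pathogen == "Coagulase-negative staphylococci"
    cultures.append(
        BloodCultureSet(
            set_id=set_id,
            patient_id=patient_id,
            ordered_at=onset,
            organisms=[pathogen],
            sirs_present=True,
            clinically_related_infection=commensal,
            infection_site="unknown",
        )
    )
    if commensal:  # two-set rule: a second positive set within 48 h
        set2 = ids.next_set()
        t2 = snap_to_grid(onset + rng.uniform(1.0, 40.0))
        cultures.append(
            BloodCultureSet(
                set_id=set2,
                patient_id=patient_id,
                ordered_at=t2,
                organisms=[pathogen],
                sirs_present=True,
                clinically_related_infection=True,
            )
        )
        asts.append(
            ASTResult(
                isolate_id=ids.next_isolate(),
                culture_set_id=set2,
                organism=pathogen,
                gram_category=gram,
                susceptibilities=dict(scen["panel"]),
                reported_at=snap_to_grid(t2 + rng.uniform(40.0, 90.0)),
                commensal_organism=True,
            )
        )
    asts.append(
        ASTResult(
            isolate_id=ids.next_isolate(),
            culture_set_id=set_id,
            organism=pathogen,
            gram_category=gram,
            susceptibilities=dict(scen["panel"]),
            reported_at=ref,
            esbl_flag=esbl,
            commensal_organism=commensal,
            consult_canceled=canceled,
            prior_consultation=prior,
        )
    )
    if ir_mech == "culture":  # positive culture at the time of death
        t3 = snap_to_grid(death - rng.uniform(5.0, 40.0))
        # a commensal pathogen needs a second set within 48 h to clear the
        # contaminant rule; non-commensals count from a single set
        n_death_sets = 2 if commensal else 1
        for j in range(n_death_sets):
            set3 = ids.next_set()
            t3j = t3 if j == 0 else snap_to_grid(min(t3 + 2.0, death))
            cultures.append(
                BloodCultureSet(
                    set_id=set3,
                    patient_id=patient_id,
                    ordered_at=t3j,
                    organisms=[pathogen],
                    sirs_present=True,
                    clinically_related_infection=commensal,
                )
            )
            asts.append(
                ASTResult(
                    isolate_id=ids.next_isolate(),
                    culture_set_id=set3,
                    organism=pathogen,
                    gram_category=gram,
                    susceptibilities=dict(scen["panel"]),
                    reported_at=snap_to_grid(t3j + 48.0),
                    commensal_organism=commensal,
                )
            )
    if new_patient:
        admissions[patient_id] = Admission(
            patient_id=patient_id,
            admitted_at=admitted,
            age_years=age,
            ed_visit_at=ed,
            discharged_at=discharged,
            death_at=death,
            icu_at_onset=icu,
            healthcare_exposure=exposure,
            iv_only_indication=iv_only,
            persistent_focus=ir_mech == "flags",
            sepsis_signs=ir_mech == "flags",
            alternative_explanation=ir_mech in ("none", "culture"),
            **flags,
        )
    else:
        # late recurrence on the same admission: extend the stay and adopt
        # this episode's clinical-course flags (the host episode has no oral
        # administrations, so its outcomes cannot depend on the flags)
        adm0 = admissions[patient_id]
        admissions[patient_id] = replace(
            adm0,
            discharged_at=discharged,
            iv_only_indication=iv_only,
            **flags,
        )
    admins.extend(ep_admins)

    # ------------------------------------------------------------------
    # truth row: event offsets recomputed with pipeline float expressions
    def resolve(t_event):
        if t_event is not None and t_event <= censor_t:
            return t_event, True, "event"
        return censor_t, False, censor_reason

    te, te_obs, te_r = resolve(t_eff)
    to, to_obs, to_r = resolve(t_opt)
    td, td_obs, td_r = resolve(t_deesc)
    ts, ts_obs, ts_r = resolve(t_ivpo)
    death30 = (not math.isnan(death)) and death <= onset + 720.0
    truth_rows.append(
        {
            "episode_id": f"{patient_id}:{set_id}",
            "patient_id": patient_id,
            "index_set_id": set_id,
            "included": True,
            "exclusion_reason": "",
            "period": period_name,
            "month": month_of(ref),
            "pathogen": pathogen,
            "gram": gram,
            "esbl_flag": esbl,
            "mrsa": mrsa,
            "acquisition": acq,
            "icu": icu,
            "empirical_category": category,
            "eff_time": te, "eff_event": te_obs, "eff_reason": te_r,
            "opt_time": to, "opt_event": to_obs, "opt_reason": to_r,
            "deesc_time": td, "deesc_event": td_obs, "deesc_reason": td_r,
            "deesc_eligible": category != CAT_INEFFECTIVE,
            "deesc_superfluous_subgroup": category == CAT_SUPERFLUOUS,
            "ivpo_time": ts, "ivpo_event": ts_obs, "ivpo_reason": ts_r,
            "ivpo_inappropriate": inappropriate_switch,
            "death30": death30,
            "infection_related_death": ir_mech in ("flags", "two_week", "culture"),
            "consult_canceled": canceled,
            "prior_consultation": prior,
        }
    )
    month_index = next(
        i for i, (lbl, _, _) in enumerate(PRE_MONTHS if period_name == "pre_program" else POST_MONTHS)
        if lbl == month_label
    ) if month_label is not None else -1
    return {
        "patient_id": patient_id,
        "onset": onset,
        "ref": ref,
        "category": category,
        "month_pos": month_index,
        "has_death": not math.isnan(death),
        "switched": switched,
        "horizon_censored": math.isnan(death) and discharged - ref >= HORIZON_H,
        "open_records": [r for r in ep_admins if math.isinf(r.stop_at)],
        "pathogen": pathogen,
        "scen": scen,
    }


def _generate_recurrence(
    spec, rng, ids, period_name, params, host, category,
    cultures, asts, admissions, admins, truth_rows,
):
    """A new positive culture of the same organism at least two weeks after
    the host episode's onset: a separate episode on the same admission."""
    for rec in host["open_records"]:
        _close_record_at(rec, host["ref"] + 260.0)
    onset2 = snap_to_grid(host["onset"] + rng.uniform(340.0, 480.0))
    _generate_episode(
        spec, rng, ids, period_name, params, None, None, None, category,
        cultures, asts, admissions, admins, truth_rows,
        patient_id=host["patient_id"], onset=onset2,
        admission=admissions[host["patient_id"]],
    )


def _generate_different_infection(
    spec, rng, ids, period_name, params, host,
    cultures, asts, admissions, admins, truth_rows,
):
    """An obviously different infection with the same organism within two
    weeks: flagged as a separate episode. The running effective therapy of
    the host covers it, so it is empirically optimal by construction."""
    patient_id = host["patient_id"]
    onset2 = snap_to_grid(host["onset"] + rng.uniform(100.0, 200.0))
    ref2 = snap_to_grid(onset2 + rng.uniform(*params.report_delay_range))
    adm = admissions[patient_id]
    discharged = max(adm.discharged_at, snap_to_grid(ref2 + 280.0))
    admissions[patient_id] = replace(adm, discharged_at=discharged)
    for rec in host["open_records"]:  # keep therapy running across both episodes
        if rec.scheduled_times and rec.scheduled_times[-1] < ref2 + 240.0:
            extra_from = rec.scheduled_times[-1] + _DOSE_H
            n = int((ref2 + 240.0 - extra_from) // _DOSE_H) + 1
            rec.scheduled_times = rec.scheduled_times + [extra_from + _DOSE_H * i for i in range(n)]
    scen = host["scen"]
    pathogen = host["pathogen"]
    from .domain import gram_category as _gram

    set_id = ids.next_set()
    cultures.append(
        BloodCultureSet(
            set_id=set_id,
            patient_id=patient_id,
            ordered_at=onset2,
            organisms=[pathogen],
            sirs_present=True,
            different_infection=True,
            infection_site="secondary_site",
        )
    )
    canceled = bool(period_name == "program" and rng.random() < params.consult_cancel_frac)
    prior = bool(
        rng.random()
        < (params.prior_consult_frac_canceled if canceled else params.prior_consult_frac_other)
    )
    asts.append(
        ASTResult(
            isolate_id=ids.next_isolate(),
            culture_set_id=set_id,
            organism=pathogen,
            gram_category=_gram(pathogen),
            susceptibilities=dict(scen["panel"]),
            reported_at=ref2,
            consult_canceled=canceled,
            prior_consultation=prior,
        )
    )
    censor_t, censor_reason = _truth_censor(ref2, ABSENT, discharged)
    truth_rows.append(
        {
            "episode_id": f"{patient_id}:{set_id}",
            "patient_id": patient_id,
            "index_set_id": set_id,
            "included": True,
            "exclusion_reason": "",
            "period": period_name,
            "month": month_of(ref2),
            "pathogen": pathogen,
            "gram": _gram(pathogen),
            "esbl_flag": False,
            "mrsa": False,
            "acquisition": "hospital_onset",
            "icu": admissions[patient_id].icu_at_onset,
            "empirical_category": CAT_OPTIMAL,
            "eff_time": 0.0, "eff_event": True, "eff_reason": "event",
            "opt_time": 0.0, "opt_event": True, "opt_reason": "event",
            "deesc_time": censor_t, "deesc_event": False, "deesc_reason": censor_reason,
            "deesc_eligible": True,
            "deesc_superfluous_subgroup": False,
            "ivpo_time": censor_t, "ivpo_event": False, "ivpo_reason": censor_reason,
            "ivpo_inappropriate": False,
            "death30": False,
            "infection_related_death": False,
            "consult_canceled": canceled,
            "prior_consultation": prior,
        }
    )


def _minimal_included_scaffold(rng, ids, params, months):
    """Onset/reference/patient scaffold for injected excluded episodes."""
    label, m0, dur = months[rng.choice(len(months))]
    patient_id = ids.next_patient()
    onset = snap_to_grid(m0 + rng.uniform(0.0, dur - 96.0))
    ref = snap_to_grid(onset + rng.uniform(*params.report_delay_range))
    return patient_id, onset, ref


def _generate_period_injections(
    spec, rng, ids, period_name, params, months,
    cultures, asts, admissions, admins, truth_rows, noise_rows,
):
    inj = spec.injections
    from .domain import gram_category as _gram

    def emit_excluded(reason, *, age=None, admitted_shift=None, discharged_rel=None,
                      death_rel=None, organisms=None):
        patient_id, onset, ref = _minimal_included_scaffold(rng, ids, params, months)
        organisms = organisms or ["Escherichia coli"]
        set_id = ids.next_set()
        cultures.append(
            BloodCultureSet(
                set_id=set_id, patient_id=patient_id, ordered_at=onset,
                organisms=list(organisms), sirs_present=True,
            )
        )
        for org in organisms:
            scen = _scenario(org, False, False, CAT_OPTIMAL)
            asts.append(
                ASTResult(
                    isolate_id=ids.next_isolate(), culture_set_id=set_id,
                    organism=org, gram_category=_gram(org),
                    susceptibilities=dict(scen["panel"]), reported_at=ref,
                )
            )
        scen = _scenario(organisms[0], False, False, CAT_OPTIMAL)
        admins.append(
            _open_record(
                patient_id, scen["N"], snap_to_grid(ref - rng.uniform(6.0, 48.0)),
                snap_to_grid(ref + 240.0),
            )
        )
        admitted = (
            snap_to_grid(onset + admitted_shift)
            if admitted_shift is not None
            else snap_to_grid(onset - rng.uniform(2.0, 40.0))
        )
        death = snap_to_grid(ref + death_rel) if death_rel is not None else ABSENT
        if discharged_rel is not None:
            discharged = snap_to_grid(ref + discharged_rel)
        elif not math.isnan(death):
            discharged = death
        else:
            discharged = snap_to_grid(ref + rng.uniform(200.0, 600.0))
        admissions[patient_id] = Admission(
            patient_id=patient_id,
            admitted_at=admitted,
            age_years=age if age is not None else round(float(rng.uniform(30.0, 85.0)), 1),
            discharged_at=discharged,
            death_at=death,
        )
        truth_rows.append(
            {
                "episode_id": f"{patient_id}:{set_id}",
                "patient_id": patient_id,
                "index_set_id": set_id,
                "included": False,
                "exclusion_reason": reason,
                "period": period_name,
                "month": month_of(ref),
                "pathogen": "|".join(sorted(organisms)),
                "gram": _gram(organisms[0]),
            }
        )

    for _ in range(inj.age_under_18):
        emit_excluded("age_under_18", age=round(float(rng.uniform(2.0, 17.0)), 1))
    for _ in range(inj.not_hospitalized):
        emit_excluded("not_hospitalized_or_ed", admitted_shift=float(rng.uniform(5.0, 20.0)))
    for _ in range(inj.discharged_before_report):
        emit_excluded("discharged_before_report", discharged_rel=-float(rng.uniform(2.0, 20.0)))
    for _ in range(inj.polymicrobial):
        emit_excluded("polymicrobial", organisms=["Escherichia coli", "Enterococcus faecalis"])
    for _ in range(inj.early_death):
        emit_excluded("early_death", death_rel=float(rng.uniform(2.0, 23.0)))

    for _ in range(inj.contaminant_sets):  # single commensal set: contaminant, no episode
        patient_id, onset, _ = _minimal_included_scaffold(rng, ids, params, months)
        set_id = ids.next_set()
        cultures.append(
            BloodCultureSet(
                set_id=set_id, patient_id=patient_id, ordered_at=onset,
                organisms=["Coagulase-negative staphylococci"],
                sirs_present=True, clinically_related_infection=False,
            )
        )
        admissions[patient_id] = Admission(
            patient_id=patient_id,
            admitted_at=snap_to_grid(onset - rng.uniform(2.0, 40.0)),
            age_years=round(float(rng.uniform(30.0, 85.0)), 1),
            discharged_at=snap_to_grid(onset + rng.uniform(100.0, 400.0)),
        )
        noise_rows.append(
            {"set_id": set_id, "patient_id": patient_id, "kind": "contaminant",
             "organism": "Coagulase-negative staphylococci"}
        )

    for _ in range(inj.sirs_absent_sets):  # positive growth without SIRS: no episode
        patient_id, onset, ref = _minimal_included_scaffold(rng, ids, params, months)
        set_id = ids.next_set()
        scen = _scenario("Escherichia coli", False, False, CAT_OPTIMAL)
        cultures.append(
            BloodCultureSet(
                set_id=set_id, patient_id=patient_id, ordered_at=onset,
                organisms=["Escherichia coli"], sirs_present=False,
            )
        )
        asts.append(
            ASTResult(
                isolate_id=ids.next_isolate(), culture_set_id=set_id,
                organism="Escherichia coli", gram_category=GRAM_NEGATIVE,
                susceptibilities=dict(scen["panel"]), reported_at=ref,
            )
        )
        admissions[patient_id] = Admission(
            patient_id=patient_id,
            admitted_at=snap_to_grid(onset - rng.uniform(2.0, 40.0)),
            age_years=round(float(rng.uniform(30.0, 85.0)), 1),
            discharged_at=snap_to_grid(onset + rng.uniform(100.0, 400.0)),
        )
        noise_rows.append(
            {"set_id": set_id, "patient_id": patient_id, "kind": "sirs_absent",
             "organism": "Escherichia coli"}
        )

    # repeat cultures inside a running episode: extra set joins, no new episode
    eligible = [
        row for row in truth_rows
        if row.get("included")
        and row["period"] == period_name
        and not row.get("death30", False)
        and row.get("pathogen") != "Coagulase-negative staphylococci"
    ]
    idx = rng.choice(len(eligible), size=min(inj.repeat_cultures, len(eligible)), replace=False)
    for i in np.atleast_1d(idx):
        row = eligible[int(i)]
        host_sets = [c for c in cultures if c.set_id == row["index_set_id"]]
        host = host_sets[0]
        host_ast = next(a for a in asts if a.culture_set_id == host.set_id)
        set_id = ids.next_set()
        t2 = snap_to_grid(host.ordered_at + rng.uniform(24.0, 120.0))
        cultures.append(
            BloodCultureSet(
                set_id=set_id, patient_id=host.patient_id, ordered_at=t2,
                organisms=list(host.organisms), sirs_present=True,
            )
        )
        asts.append(
            ASTResult(
                isolate_id=ids.next_isolate(), culture_set_id=set_id,
                organism=host_ast.organism, gram_category=host_ast.gram_category,
                susceptibilities=dict(host_ast.susceptibilities),
                reported_at=snap_to_grid(t2 + rng.uniform(40.0, 90.0)),
                esbl_flag=host_ast.esbl_flag,
            )
        )
        noise_rows.append(
            {"set_id": set_id, "patient_id": host.patient_id, "kind": "repeat_culture",
             "organism": host_ast.organism}
        )


def _generate_initiation_month(spec, rng, ids, cultures, asts, admissions, admins, truth_rows):
    """Episodes with onset in the program-initiation month (excluded)."""
    from .domain import gram_category as _gram

    label, m0, dur = INITIATION
    for _ in range(spec.initiation_month_episodes):
        patient_id = ids.next_patient()
        onset = snap_to_grid(m0 + rng.uniform(0.0, dur - 96.0))
        ref = snap_to_grid(onset + rng.uniform(40.0, 90.0))
        set_id = ids.next_set()
        scen = _scenario("Escherichia coli", False, False, CAT_OPTIMAL)
        cultures.append(
            BloodCultureSet(
                set_id=set_id, patient_id=patient_id, ordered_at=onset,
                organisms=["Escherichia coli"], sirs_present=True,
            )
        )
        asts.append(
            ASTResult(
                isolate_id=ids.next_isolate(), culture_set_id=set_id,
                organism="Escherichia coli", gram_category=GRAM_NEGATIVE,
                susceptibilities=dict(scen["panel"]), reported_at=ref,
            )
        )
        admins.append(
            _open_record(
                patient_id, scen["N"], snap_to_grid(ref - rng.uniform(6.0, 48.0)),
                snap_to_grid(ref + 240.0),
            )
        )
        admissions[patient_id] = Admission(
            patient_id=patient_id,
            admitted_at=snap_to_grid(onset - rng.uniform(2.0, 40.0)),
            age_years=round(float(rng.uniform(30.0, 85.0)), 1),
            discharged_at=snap_to_grid(onset + rng.uniform(300.0, 700.0)),
        )
        truth_rows.append(
            {
                "episode_id": f"{patient_id}:{set_id}",
                "patient_id": patient_id,
                "index_set_id": set_id,
                "included": False,
                "exclusion_reason": "initiation_month",
                "period": "pre_program" if onset < datetime_to_hours(PROGRAM_START) else "program",
                "month": month_of(ref),
                "pathogen": "Escherichia coli",
                "gram": GRAM_NEGATIVE,
            }
        )
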