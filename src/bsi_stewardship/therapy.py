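"""Classify the antimicrobial regimen of each episode over time.

All time-to-event outcomes are measured from the reference time (the ID/AST
report). The regimen at a time t is:

* effective      — at least one in-use agent with susceptibility S for the
                   episode pathogen ("I" is conservatively counted as not
                   active);
* superfluous    — some in-use agent is on the designated broad-spectrum
                   list for the pathogen's gram category while the pathogen
                   is susceptible to at least one non-superfluous agent of
                   the same category in the formulary (the spectrum is
                   excessive);
* optimal        — effective, not superfluous, and at least one in-use
                   active agent is adequate in site, dose and route (IV, or
                   oral while all five IV-to-oral criteria hold).

Discontinuation of an agent is imputed at the next scheduled administration
after its last given dose; an agent counts as in use on [start, stop).
De-escalation is the discontinuation of a broad agent together with the
administration of a strictly narrower-spectrum active agent; the event time
is the later of the two actions. Everything is censored at 240 h after the
reference time, or earlier at death or discharge (precedence at ties:
event > death > discharge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .domain import (
    Admission,
    AdministrationRecord,
    ASTResult,
    Episode,
    KnowledgeBase,
    PO,
    is_absent,
    month_of,
)

HORIZON_H = 240.0

CAT_INEFFECTIVE = "ineffective"
CAT_SUPERFLUOUS = "effective_superfluous"
CAT_OTHER = "effective_other_nonoptimal"
CAT_OPTIMAL = "optimal"

CENSOR_EVENT = "event"
CENSOR_HORIZON = "horizon_240h"
CENSOR_DEATH = "death"
CENSOR_DISCHARGE = "discharge"


@dataclass(frozen=True)
class RegimenState:
    at: float
    effective: bool
    superfluous: bool
    optimal: bool

    @property
    def category(self) -> str:
        if not self.effective:
            return CAT_INEFFECTIVE
        if self.optimal:
            return CAT_OPTIMAL
        if self.superfluous:
            return CAT_SUPERFLUOUS
        return CAT_OTHER

    def __post_init__(self):
        if self.optimal and (not self.effective or self.superfluous):
            raise ValueError("optimal state must be effective and not superfluous")


def discontinuation_time(record: AdministrationRecord) -> float:
    """Imputed stop: the next scheduled administration after the last given
    dose (``inf`` for running orders)."""
    if math.isinf(record.stop_at):
        return math.inf
    times = record.scheduled_times
    if len(times) >= 2:
        return times[-1] + (times[-1] - times[-2])
    return record.stop_at


def in_use_at(record: AdministrationRecord, t: float) -> bool:
    return record.start_at <= t < discontinuation_time(record)


def ivpo_criteria_met(admission: Admission, t: float) -> bool:
    """All five appropriateness criteria for an IV-to-oral switch."""
    return (
        not admission.iv_only_indication
        and admission.afebrile.at(t)
        and admission.inflammatory_markers_decreasing.at(t)
        and admission.symptoms_improving.at(t)
        and admission.oral_intake_normal.at(t)
    )


def _route_adequate(record: AdministrationRecord, admission: Admission, t: float) -> bool:
    if record.route != PO:
        return True
    return ivpo_criteria_met(admission, t)


def classify_regimen_at(
    t: float,
    episode: Episode,
    administrations: list[AdministrationRecord],
    ast: ASTResult,
    admission: Admission,
    kb: KnowledgeBase,
) -> RegimenState:
    if t < episode.onset_at:
        raise ValueError("cannot classify before episode onset")
    if not ast.susceptibilities:
        raise ValueError(f"empty susceptibility panel for isolate {ast.isolate_id}")
    in_use = [r for r in administrations if in_use_at(r, t)]
    for r in in_use:
        if r.agent_code not in kb:
            raise KeyError(f"agent code not in knowledge base: {r.agent_code!r}")

    def active(r: AdministrationRecord) -> bool:
        return ast.susceptibilities.get(r.agent_code) == "S"

    effective = any(active(r) for r in in_use)
    superfluous = any(
        kb[r.agent_code].superfluous_for(episode.gram) for r in in_use
    ) and kb.has_nonsuperfluous_active(episode.gram, ast.susceptibilities)
    optimal = (
        effective
        and not superfluous
        and any(
            active(r)
            and r.site_adequate
            and r.dose_adequate
            and _route_adequate(r, admission, t)
            for r in in_use
        )
    )
    return RegimenState(at=t, effective=effective, superfluous=superfluous, optimal=optimal)


def censor_for(episode: Episode, horizon_h: float = HORIZON_H) -> tuple[float, str]:
    """Censoring time (hours from reference) and reason; event precedence is
    applied by the callers."""
    c_death = (
        episode.death_at - episode.reference_at
        if not is_absent(episode.death_at)
        else math.inf
    )
    c_disc = (
        episode.discharged_at - episode.reference_at
        if not math.isinf(episode.discharged_at)
        else math.inf
    )
    c = min(horizon_h, c_death, c_disc)
    if c_death == c:  # death wins ties against discharge and horizon
        return c, CENSOR_DEATH
    if c_disc == c:
        return c, CENSOR_DISCHARGE
    return c, CENSOR_HORIZON


def _resolve(event_t: float | None, censor_t: float, censor_reason: str) -> tuple[float, bool, str]:
    """(time, observed, reason) with event taking precedence at ties."""
    if event_t is not None and event_t <= censor_t:
        return event_t, True, CENSOR_EVENT
    return censor_t, False, censor_reason


def _candidate_times(
    episode: Episode,
    administrations: list[AdministrationRecord],
    admission: Admission,
    horizon_h: float,
) -> list[float]:
    ref = episode.reference_at
    out = {ref}
    for r in administrations:
        for t in (r.start_at, discontinuation_time(r)):
            if ref <= t <= ref + horizon_h and not math.isinf(t):
                out.add(t)
    for flag in (
        admission.afebrile,
        admission.inflammatory_markers_decreasing,
        admission.symptoms_improving,
        admission.oral_intake_normal,
    ):
        t = flag.true_from
        if not math.isinf(t) and ref <= t <= ref + horizon_h:
            out.add(t)
    return sorted(out)


def time_to_effective(
    episode: Episode,
    administrations: list[AdministrationRecord],
    ast: ASTResult,
    admission: Admission,
    kb: KnowledgeBase,
    horizon_h: float = HORIZON_H,
) -> tuple[float, bool, str]:
    """0 if empirical therapy is effective, else the first administration of
    an active agent after the reference time; censored otherwise."""
    ref = episode.reference_at
    censor_t, censor_reason = censor_for(episode, horizon_h)
    state = classify_regimen_at(ref, episode, administrations, ast, admission, kb)
    if state.effective:
        return _resolve(0.0, censor_t, censor_reason)
    starts = [
        r.start_at - ref
        for r in administrations
        if r.start_at > ref and ast.susceptibilities.get(r.agent_code) == "S"
    ]
    return _resolve(min(starts) if starts else None, censor_t, censor_reason)


def time_to_optimal(
    episode: Episode,
    administrations: list[AdministrationRecord],
    ast: ASTResult,
    admission: Admission,
    kb: KnowledgeBase,
    horizon_h: float = HORIZON_H,
) -> tuple[float, bool, str]:
    """First time (from the reference) at which the regimen is optimal."""
    ref = episode.reference_at
    censor_t, censor_reason = censor_for(episode, horizon_h)
    event = None
    for t in _candidate_times(episode, administrations, admission, horizon_h):
        if classify_regimen_at(t, episode, administrations, ast, admission, kb).optimal:
            event = t - ref
            break
    return _resolve(event, censor_t, censor_reason)


def time_to_deescalation(
    episode: Episode,
    administrations: list[AdministrationRecord],
    ast: ASTResult,
    kb: KnowledgeBase,
    horizon_h: float = HORIZON_H,
) -> tuple[float, bool, str]:
    """De-escalation: a broad agent in use at the reference time is
    discontinued and a strictly narrower active agent is administered; the
    event is the later of the two actions. The narrower agent need not be
    the narrowest available."""
    ref = episode.reference_at
    censor_t, censor_reason = censor_for(episode, horizon_h)
    gram = episode.gram
    candidates = []
    for broad in administrations:
        rank_b = kb[broad.agent_code].rank(gram) if broad.agent_code in kb else None
        disc = discontinuation_time(broad)
        if rank_b is None or math.isinf(disc) or disc <= ref or broad.start_at > ref:
            continue  # only agents in use at the reference and actually stopped
        for narrow in administrations:
            rank_n = kb[narrow.agent_code].rank(gram) if narrow.agent_code in kb else None
            if rank_n is None or rank_n >= rank_b:
                continue
            if ast.susceptibilities.get(narrow.agent_code) != "S":
                continue  # the narrower agent must be active in vitro
            event_at = max(disc, narrow.start_at)
            if discontinuation_time(narrow) <= event_at:
                continue  # narrower therapy must still run when the switch completes
            event = event_at - ref
            if event >= 0:
                candidates.append(event)
    return _resolve(min(candidates) if candidates else None, censor_t, censor_reason)


def time_to_ivpo_switch(
    episode: Episode,
    administrations: list[AdministrationRecord],
    ast: ASTResult,
    admission: Admission,
    kb: KnowledgeBase,
    horizon_h: float = HORIZON_H,
) -> tuple[float, bool, str, bool]:
    """First oral administration of an in-vitro-active agent while all five
    appropriateness criteria hold. Returns (time, observed, reason,
    inappropriate_switch_seen)."""
    ref = episode.reference_at
    censor_t, censor_reason = censor_for(episode, horizon_h)
    event = None
    inappropriate = False
    for r in sorted(administrations, key=lambda r: r.start_at):
        if r.route != PO or r.start_at <= ref or r.start_at - ref > censor_t:
            continue  # only switches inside this episode's observation window
        if ast.susceptibilities.get(r.agent_code) != "S":
            continue
        if ivpo_criteria_met(admission, r.start_at):
            event = r.start_at - ref
            break
        inappropriate = True
    t, observed, reason = _resolve(event, censor_t, censor_reason)
    return t, observed, reason, inappropriate


def label_infection_related_death(
    episode: Episode,
    admission: Admission,
    culture_sets: list,
    documentation_window_h: float = 336.0,
    culture_at_death_window_h: float = 48.0,
) -> bool:
    """Infection-related death adjudication: a positive (non-contaminant)
    blood culture at the time of death, a persistent focus with sepsis
    signs, or death within two weeks of BSI documentation without an
    alternative explanation."""
    if is_absent(admission.death_at):
        return False
    death = admission.death_at
    positive_at_death = any(
        cs.patient_id == episode.patient_id
        and cs.pathogens()
        and death - culture_at_death_window_h <= cs.ordered_at <= death
        for cs in culture_sets
    )
    if positive_at_death:
        return True
    if admission.persistent_focus and admission.sepsis_signs:
        return True
    if death <= episode.reference_at + documentation_window_h and not admission.alternative_explanation:
        return True
    return False


def build_outcome_table(
    episodes: list[Episode],
    admissions: dict[str, Admission],
    asts_by_set: dict[str, ASTResult],
    administrations_by_patient: dict[str, list[AdministrationRecord]],
    culture_sets: list,
    kb: KnowledgeBase,
    horizon_h: float = HORIZON_H,
) -> pd.DataFrame:
    """Per-episode outcome table for included episodes: empirical category,
    the four event/censor times with reasons, and mortality labels. This is
    the direct input to the survival and ITS stages."""
    rows = []
    for ep in episodes:
        if ep.excluded:
            continue
        adm = admissions[ep.patient_id]
        ast = asts_by_set[ep.index_set_id]
        admins = administrations_by_patient.get(ep.patient_id, [])
        empirical = classify_regimen_at(ep.reference_at, ep, admins, ast, adm, kb)
        te, te_obs, te_reason = time_to_effective(ep, admins, ast, adm, kb, horizon_h)
        to, to_obs, to_reason = time_to_optimal(ep, admins, ast, adm, kb, horizon_h)
        td, td_obs, td_reason = time_to_deescalation(ep, admins, ast, kb, horizon_h)
        ts, ts_obs, ts_reason, ts_bad = time_to_ivpo_switch(ep, admins, ast, adm, kb, horizon_h)
        death30 = (not is_absent(adm.death_at)) and adm.death_at <= ep.onset_at + 720.0
        rows.append(
            {
                "episode_id": ep.episode_id,
                "patient_id": ep.patient_id,
                "period": ep.period,
                "month": month_of(ep.reference_at),
                "reference_at": ep.reference_at,
                "pathogen": ep.pathogen,
                "gram": ep.gram,
                "esbl_flag": ep.esbl_flag,
                "acquisition": ep.acquisition,
                "icu": adm.icu_at_onset,
                "age_years": adm.age_years,
                "empirical_category": empirical.category,
                "empirical_effective": empirical.effective,
                "empirical_superfluous": empirical.category == CAT_SUPERFLUOUS,
                "empirical_optimal": empirical.optimal,
                "eff_time": te,
                "eff_event": te_obs,
                "eff_reason": te_reason,
                "opt_time": to,
                "opt_event": to_obs,
                "opt_reason": to_reason,
                "deesc_time": td,
                "deesc_event": td_obs,
                "deesc_reason": td_reason,
                "deesc_eligible": empirical.effective,
                "deesc_superfluous_subgroup": empirical.category == CAT_SUPERFLUOUS,
                "ivpo_time": ts,
                "ivpo_event": ts_obs,
                "ivpo_reason": ts_reason,
                "ivpo_inappropriate": ts_bad,
                "death30": death30,
                "infection_related_death": death30
                and label_infection_related_death(ep, adm, culture_sets),
                "death_outcome": not is_absent(adm.death_at),
                "los_h": (
                    adm.discharged_at - adm.admitted_at
                    if not math.isinf(adm.discharged_at)
                    else float("nan")
                ),
                "consult_canceled": ep.consult_canceled,
                "prior_consultation": ep.prior_consultation,
            }
        )
    return pd.DataFrame(rows)
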