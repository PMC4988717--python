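"""Build included BSI episodes from raw culture/admission records.

An episode is growth of a pathogen from one or more culture sets in a
patient with SIRS. Skin commensals (coagulase-negative staphylococci,
Corynebacterium) count as pathogens only when two or more sets are positive
for them within 48 hours and a clinically related infection is recorded.
Positive cultures of the same organism within two weeks of onset belong to
one episode; a culture at or beyond two weeks — or one flagged as an
obviously different infection — opens a new episode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .domain import (
    INITIATION_MONTH,
    PROGRAM_START,
    Admission,
    ASTResult,
    BloodCultureSet,
    Episode,
    datetime_to_hours,
    gram_category,
    hours_to_datetime,
    is_absent,
    is_commensal,
)

COMMUNITY = "community"
HEALTHCARE_ASSOCIATED = "healthcare_associated"
HOSPITAL_ONSET = "hospital_onset"

# exclusion reasons, in precedence order
REASON_AGE = "age_under_18"
REASON_LOCATION = "not_hospitalized_or_ed"
REASON_DISCHARGE = "discharged_before_report"
REASON_POLYMICROBIAL = "polymicrobial"
REASON_EARLY_DEATH = "early_death"
REASON_INITIATION_MONTH = "initiation_month"
EXCLUSION_PRECEDENCE = (
    REASON_AGE,
    REASON_LOCATION,
    REASON_DISCHARGE,
    REASON_POLYMICROBIAL,
    REASON_EARLY_DEATH,
    REASON_INITIATION_MONTH,
)


@dataclass
class EpisodeBuildConfig:
    commensal_window_h: float = 48.0
    new_episode_gap_h: float = 336.0  # two weeks; a culture at exactly 336 h is a new episode
    nosocomial_cutoff_h: float = 48.0
    early_death_window_h: float = 24.0
    adult_age_min: float = 18.0
    program_start_h: float = field(default_factory=lambda: datetime_to_hours(PROGRAM_START))
    exclusion_month: tuple[int, int] = INITIATION_MONTH

    def __post_init__(self):
        for name in ("commensal_window_h", "new_episode_gap_h", "nosocomial_cutoff_h", "early_death_window_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def flag_contaminants(
    culture_sets: list[BloodCultureSet], config: EpisodeBuildConfig
) -> list[BloodCultureSet]:
    """Mark commensal organisms as contaminants unless the two-set rule holds.

    A commensal counts as a pathogen iff >=2 sets of the same patient are
    positive for it within ``commensal_window_h`` of each other AND at least
    one of those sets carries the clinically-related-infection flag.
    Non-commensal organisms are never flagged. Unknown organisms raise.
    """
    by_patient: dict[str, list[BloodCultureSet]] = {}
    for cs in culture_sets:
        for org in cs.organisms:
            is_commensal(org)  # raises on unknown organism, naming the record
        by_patient.setdefault(cs.patient_id, []).append(cs)

    for sets in by_patient.values():
        sets = sorted(sets, key=lambda s: s.ordered_at)
        for cs in sets:
            for org in cs.organisms:
                if not is_commensal(org):
                    continue
                near = [
                    other
                    for other in sets
                    if org in other.organisms
                    and abs(other.ordered_at - cs.ordered_at) <= config.commensal_window_h
                ]
                clinical = any(o.clinically_related_infection for o in near)
                if len(near) >= 2 and clinical:
                    cs.contaminant_organisms.discard(org)
                else:
                    cs.contaminant_organisms.add(org)
    return culture_sets


def _episode_period(onset_at: float, config: EpisodeBuildConfig) -> str:
    return "pre_program" if onset_at < config.program_start_h else "program"


def build_episodes(
    culture_sets: list[BloodCultureSet],
    admissions: dict[str, Admission],
    ast_results: list[ASTResult],
    config: EpisodeBuildConfig,
) -> list[Episode]:
    """Group non-contaminant positive cultures into episodes.

    Requires contaminants already flagged and every pathogen-positive set
    linked to an AST result. Episodes anchored at the first culture order
    (onset) and the index isolate's report time (reference). Sets positive
    for two or more pathogens form a single polymicrobial episode (excluded
    downstream).
    """
    ast_by_set: dict[str, list[ASTResult]] = {}
    for ast in ast_results:
        ast_by_set.setdefault(ast.culture_set_id, []).append(ast)

    episodes: list[Episode] = []
    by_patient: dict[str, list[BloodCultureSet]] = {}
    for cs in culture_sets:
        by_patient.setdefault(cs.patient_id, []).append(cs)

    for patient_id in sorted(by_patient):
        sets = sorted(by_patient[patient_id], key=lambda s: (s.ordered_at, s.set_id))
        # cluster key: the organism for monomicrobial growth, the sorted
        # organism tuple for polymicrobial growth
        open_onsets: dict[tuple, float] = {}
        for cs in sets:
            pathogens = cs.pathogens()
            if not pathogens or not cs.sirs_present:
                continue
            if cs.set_id not in ast_by_set:
                raise ValueError(
                    f"positive culture set without AST linkage: {cs.set_id}"
                )
            key = tuple(sorted(pathogens))
            onset = open_onsets.get(key)
            new_episode = (
                onset is None
                or cs.ordered_at - onset >= config.new_episode_gap_h
                or cs.different_infection
            )
            if not new_episode:
                continue  # repeat culture of the running episode
            open_onsets[key] = cs.ordered_at
            index_asts = sorted(ast_by_set[cs.set_id], key=lambda a: a.reported_at)
            index_ast = next(
                (a for a in index_asts if a.organism == pathogens[0]), index_asts[0]
            )
            adm = admissions.get(patient_id)
            episodes.append(
                Episode(
                    episode_id=f"{patient_id}:{cs.set_id}",
                    patient_id=patient_id,
                    onset_at=cs.ordered_at,
                    reference_at=index_ast.reported_at,
                    pathogen="|".join(key),
                    gram=gram_category(pathogens[0]),
                    period=_episode_period(cs.ordered_at, config),
                    infection_site=cs.infection_site,
                    index_set_id=cs.set_id,
                    polymicrobial=len(pathogens) >= 2,
                    esbl_flag=index_ast.esbl_flag,
                    consult_canceled=index_ast.consult_canceled,
                    prior_consultation=index_ast.prior_consultation,
                    death_at=adm.death_at if adm else float("nan"),
                    discharged_at=adm.discharged_at if adm else float("inf"),
                )
            )
    return episodes


def classify_acquisition(
    episode: Episode, admission: Admission, config: EpisodeBuildConfig
) -> str:
    """Community / healthcare-associated / hospital-onset, from the interval
    between admission (or ED visit when admitted via ED) and onset."""
    clock = admission.ed_visit_at if not is_absent(admission.ed_visit_at) else admission.admitted_at
    delta = episode.onset_at - clock
    if delta < 0:
        raise ValueError(
            f"episode {episode.episode_id}: onset precedes admission/ED clock"
        )
    if delta >= config.nosocomial_cutoff_h:
        return HOSPITAL_ONSET
    return HEALTHCARE_ASSOCIATED if admission.healthcare_exposure else COMMUNITY


def _in_hospital_at(admission: Admission, t: float) -> bool:
    clock = admission.ed_visit_at if not is_absent(admission.ed_visit_at) else admission.admitted_at
    end = admission.discharged_at
    return clock <= t and (math.isinf(end) or t <= end)


def apply_exclusions(
    episodes: list[Episode],
    admissions: dict[str, Admission],
    config: EpisodeBuildConfig,
) -> list[Episode]:
    """Label exclusions with a fixed reason precedence:
    age -> location -> discharge-before-report -> polymicrobial ->
    early death -> initiation month."""
    for ep in episodes:
        adm = admissions[ep.patient_id]
        reason = ""
        onset_month = hours_to_datetime(ep.onset_at)
        if adm.age_years < config.adult_age_min:
            reason = REASON_AGE
        elif not _in_hospital_at(adm, ep.onset_at):
            reason = REASON_LOCATION
        elif (
            not math.isinf(adm.discharged_at)
            and adm.discharged_at < ep.reference_at
            and not (not is_absent(adm.death_at) and adm.death_at <= adm.discharged_at)
        ):
            reason = REASON_DISCHARGE
        elif ep.polymicrobial:
            reason = REASON_POLYMICROBIAL
        elif (
            not is_absent(adm.death_at)
            and adm.death_at <= ep.reference_at + config.early_death_window_h
        ):
            reason = REASON_EARLY_DEATH
        elif (onset_month.year, onset_month.month) == config.exclusion_month:
            reason = REASON_INITIATION_MONTH
        ep.excluded = bool(reason)
        ep.exclusion_reason = reason
        if not ep.excluded:
            ep.acquisition = classify_acquisition(ep, adm, config)
    return episodes


def episode_table(episodes: list[Episode]) -> pd.DataFrame:
    """One row per episode, including exclusion accounting."""
    rows = []
    for ep in episodes:
        rows.append(
            {
                "episode_id": ep.episode_id,
                "patient_id": ep.patient_id,
                "onset_at": ep.onset_at,
                "reference_at": ep.reference_at,
                "pathogen": ep.pathogen,
                "gram": ep.gram,
                "acquisition": ep.acquisition,
                "period": ep.period,
                "excluded": ep.excluded,
                "exclusion_reason": ep.exclusion_reason,
                "infection_site": ep.infection_site,
                "polymicrobial": ep.polymicrobial,
                "esbl_flag": ep.esbl_flag,
                "consult_canceled": ep.consult_canceled,
                "prior_consultation": ep.prior_consultation,
            }
        )
    return pd.DataFrame(rows)


def flow_counts(
    culture_sets: list[BloodCultureSet], episodes: list[Episode]
) -> dict[str, int]:
    """Subject-selection flow summary: sets, contaminant-only sets, episodes
    identified, exclusions by reason, included per period."""
    positive = [cs for cs in culture_sets if cs.organisms]
    contaminant_only = [cs for cs in positive if not cs.pathogens()]
    counts = {
        "culture_sets_positive": len(positive),
        "culture_sets_contaminant_only": len(contaminant_only),
        "episodes_identified": len(episodes),
    }
    for reason in EXCLUSION_PRECEDENCE:
        counts[f"excluded_{reason}"] = sum(
            1 for ep in episodes if ep.exclusion_reason == reason
        )
    counts["excluded_total"] = sum(1 for ep in episodes if ep.excluded)
    for period in ("pre_program", "program"):
        counts[f"included_{period}"] = sum(
            1 for ep in episodes if not ep.excluded and ep.period == period
        )
    return counts
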