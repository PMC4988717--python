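"""Regimen classification, event-time derivation and mortality labels."""

import math

import pytest

from bsi_stewardship.domain import (
    ABSENT,
    Admission,
    AdministrationRecord,
    ASTResult,
    BloodCultureSet,
    Episode,
    KnowledgeBase,
    StepFlag,
)
from bsi_stewardship.therapy import (
    CAT_INEFFECTIVE,
    CAT_OPTIMAL,
    CAT_OTHER,
    CAT_SUPERFLUOUS,
    RegimenState,
    classify_regimen_at,
    discontinuation_time,
    label_infection_related_death,
    time_to_deescalation,
    time_to_effective,
    time_to_ivpo_switch,
    time_to_optimal,
)

KB = KnowledgeBase()
REF = 100.0


def _episode(gram="gram_positive", pathogen="Staphylococcus aureus"):
    return Episode(
        episode_id="e", patient_id="p", onset_at=40.0, reference_at=REF,
        pathogen=pathogen, gram=gram, discharged_at=math.inf,
    )


def _ast(susc, organism="Staphylococcus aureus", gram="gram_positive"):
    return ASTResult(
        isolate_id="i", culture_set_id="s", organism=organism,
        gram_category=gram, susceptibilities=susc, reported_at=REF,
    )


def _adm(**kw):
    defaults = dict(patient_id="p", admitted_at=0.0, age_years=60.0)
    defaults.update(kw)
    return Admission(**defaults)


def _rec(agent, start, stop=math.inf, doses=None, route="IV", **kw):
    return AdministrationRecord(
        patient_id="p", agent_code=agent, route=route, start_at=start,
        stop_at=stop, scheduled_times=doses or [start], **kw
    )


class TestClassifyRegimen:
    def test_mssa_on_vancomycin_is_effective_superfluous(self):
        """Glycopeptide empirical therapy against MSSA: active but broader
        than needed, hence effective, superfluous, non-optimal."""
        ast = _ast({"VAN": "S", "CFZ": "S", "NAF": "S"})
        state = classify_regimen_at(REF, _episode(), [_rec("VAN", 50.0)], ast, _adm(), KB)
        assert state.effective and state.superfluous and not state.optimal
        assert state.category == CAT_SUPERFLUOUS

    def test_esbl_on_ceftriaxone_is_ineffective(self):
        ast = _ast({"CRO": "R", "MEM": "S"}, organism="Escherichia coli", gram="gram_negative")
        ep = _episode(gram="gram_negative", pathogen="Escherichia coli")
        state = classify_regimen_at(REF, ep, [_rec("CRO", 50.0)], ast, _adm(), KB)
        assert state.category == CAT_INEFFECTIVE

    def test_pan_susceptible_on_meropenem_is_superfluous(self):
        ast = _ast({"MEM": "S", "CRO": "S"}, organism="Escherichia coli", gram="gram_negative")
        ep = _episode(gram="gram_negative", pathogen="Escherichia coli")
        state = classify_regimen_at(REF, ep, [_rec("MEM", 50.0)], ast, _adm(), KB)
        assert state.effective and state.superfluous

    def test_mrsa_on_vancomycin_is_optimal(self):
        """No narrower active alternative exists, so the glycopeptide is not
        superfluous and adequate therapy is optimal."""
        ast = _ast({"VAN": "S", "CFZ": "R", "NAF": "R"})
        state = classify_regimen_at(REF, _episode(), [_rec("VAN", 50.0)], ast, _adm(), KB)
        assert state.category == CAT_OPTIMAL

    def test_inadequate_dose_blocks_optimality(self):
        ast = _ast({"CFZ": "S"})
        recs = [_rec("CFZ", 50.0, dose_adequate=False)]
        state = classify_regimen_at(REF, _episode(), recs, ast, _adm(), KB)
        assert state.category == CAT_OTHER

    def test_intermediate_susceptibility_not_active(self):
        ast = _ast({"CFZ": "I"})
        state = classify_regimen_at(REF, _episode(), [_rec("CFZ", 50.0)], ast, _adm(), KB)
        assert not state.effective

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError, match="empty susceptibility"):
            classify_regimen_at(REF, _episode(), [], _ast({}), _adm(), KB)

    def test_state_invariant_enforced(self):
        with pytest.raises(ValueError):
            RegimenState(at=0.0, effective=True, superfluous=True, optimal=True)

    def test_idempotent(self):
        ast = _ast({"VAN": "S", "CFZ": "S"})
        recs = [_rec("VAN", 50.0)]
        s1 = classify_regimen_at(REF, _episode(), recs, ast, _adm(), KB)
        s2 = classify_regimen_at(REF, _episode(), recs, ast, _adm(), KB)
        assert s1 == s2


class TestTimeToEffective:
    def test_empirically_effective_is_zero(self):
        ast = _ast({"CFZ": "S"})
        t, obs, reason = time_to_effective(_episode(), [_rec("CFZ", 50.0)], ast, _adm(), KB)
        assert (t, obs, reason) == (0.0, True, "event")

    def test_first_active_dose_after_reporting(self):
        ast = _ast({"CFZ": "S", "AMP": "R"})
        recs = [_rec("AMP", 50.0), _rec("CFZ", REF + 12.0)]
        t, obs, _ = time_to_effective(_episode(), recs, ast, _adm(), KB)
        assert (t, obs) == (12.0, True)

    def test_no_active_agent_before_discharge_censors(self):
        ast = _ast({"AMP": "R"})
        ep = _episode()
        ep.discharged_at = REF + 100.0
        t, obs, reason = time_to_effective(ep, [_rec("AMP", 50.0)], ast, _adm(), KB)
        assert (t, obs, reason) == (100.0, False, "discharge")

    def test_death_beats_discharge_at_same_time(self):
        ast = _ast({"AMP": "R"})
        ep = _episode()
        ep.discharged_at = REF + 50.0
        ep.death_at = REF + 50.0
        t, obs, reason = time_to_effective(ep, [_rec("AMP", 50.0)], ast, _adm(), KB)
        assert (t, obs, reason) == (50.0, False, "death")


class TestDeescalation:
    def test_discontinuation_imputed_at_next_scheduled_dose(self):
        """Last meropenem dose 08:00, q8h schedule: stopping the order means
        discontinuation at 16:00; with the narrower agent already started at
        12:00 the event is at 16:00."""
        broad = _rec("MEM", 80.0, stop=REF + 16.0, doses=[80.0, 88.0, 96.0, REF + 0.0, REF + 8.0])
        assert discontinuation_time(broad) == REF + 16.0
        narrow = _rec("CRO", REF + 12.0)
        ast = _ast({"MEM": "S", "CRO": "S"}, organism="Escherichia coli", gram="gram_negative")
        ep = _episode(gram="gram_negative", pathogen="Escherichia coli")
        t, obs, _ = time_to_deescalation(ep, [broad, narrow], ast, KB)
        assert (t, obs) == (16.0, True)

    def test_switch_to_equally_broad_agent_is_no_event(self):
        broad = _rec("MEM", 80.0, stop=REF + 16.0, doses=[80.0, 88.0, 96.0, REF, REF + 8.0])
        other = _rec("IPM", REF + 8.0)
        ast = _ast({"MEM": "S", "IPM": "S"}, organism="Escherichia coli", gram="gram_negative")
        ep = _episode(gram="gram_negative", pathogen="Escherichia coli")
        t, obs, reason = time_to_deescalation(ep, [broad, other], ast, KB)
        assert not obs and reason == "horizon_240h"

    def test_narrower_agent_already_coadministered(self):
        """Stopping the broad agent at +30 h completes the de-escalation."""
        broad = _rec("MEM", 66.0, stop=REF + 30.0, doses=[66.0 + 8 * i for i in range(8)])
        narrow = _rec("CRO", 90.0)
        ast = _ast({"MEM": "S", "CRO": "S"}, organism="Escherichia coli", gram="gram_negative")
        ep = _episode(gram="gram_negative", pathogen="Escherichia coli")
        t, obs, _ = time_to_deescalation(ep, [broad, narrow], ast, KB)
        assert (t, obs) == (30.0, True)

    def test_narrower_agent_must_be_active(self):
        broad = _rec("MEM", 80.0, stop=REF + 16.0, doses=[80.0, 88.0, 96.0, REF, REF + 8.0])
        narrow = _rec("CRO", REF + 12.0)
        ast = _ast({"MEM": "S", "CRO": "R"}, organism="Escherichia coli", gram="gram_negative")
        ep = _episode(gram="gram_negative", pathogen="Escherichia coli")
        _, obs, _ = time_to_deescalation(ep, [broad, narrow], ast, KB)
        assert not obs


class TestIvPoSwitch:
    def _setup(self, oral_from=0.0, iv_only=False):
        adm = _adm(
            afebrile=StepFlag(0.0),
            inflammatory_markers_decreasing=StepFlag(0.0),
            symptoms_improving=StepFlag(0.0),
            oral_intake_normal=StepFlag(oral_from),
            iv_only_indication=iv_only,
        )
        ast = _ast({"CFZ": "S", "LEX-PO": "S"})
        return adm, ast

    def test_switch_with_all_criteria_met(self):
        adm, ast = self._setup()
        recs = [_rec("CFZ", 50.0), _rec("LEX-PO", REF + 72.0, route="PO")]
        t, obs, _, bad = time_to_ivpo_switch(_episode(), recs, ast, adm, KB)
        assert (t, obs, bad) == (72.0, True, False)

    def test_switch_during_vomiting_is_not_an_event(self):
        adm, ast = self._setup(oral_from=math.inf)
        recs = [_rec("CFZ", 50.0), _rec("LEX-PO", REF + 72.0, route="PO")]
        t, obs, reason, bad = time_to_ivpo_switch(_episode(), recs, ast, adm, KB)
        assert not obs and reason == "horizon_240h" and bad

    def test_iv_only_indication_blocks_switch(self):
        adm, ast = self._setup(iv_only=True)
        recs = [_rec("CFZ", 50.0), _rec("LEX-PO", REF + 72.0, route="PO")]
        _, obs, _, bad = time_to_ivpo_switch(_episode(), recs, ast, adm, KB)
        assert not obs and bad

    def test_never_switched_censors_at_horizon(self):
        adm, ast = self._setup()
        t, obs, reason, bad = time_to_ivpo_switch(_episode(), [_rec("CFZ", 50.0)], ast, adm, KB)
        assert (t, obs, reason, bad) == (240.0, False, "horizon_240h", False)


class TestInfectionRelatedDeath:
    def _cs(self, t):
        return BloodCultureSet(
            set_id="x", patient_id="p", ordered_at=t, organisms=["Escherichia coli"]
        )

    def test_positive_culture_at_death(self):
        adm = _adm(death_at=REF + 200.0, alternative_explanation=True)
        assert label_infection_related_death(_episode(), adm, [self._cs(REF + 180.0)])

    def test_death_without_criteria(self):
        adm = _adm(death_at=REF + 480.0, alternative_explanation=True)  # day 20
        assert not label_infection_related_death(_episode(), adm, [])

    def test_death_within_two_weeks_without_alternative(self):
        adm = _adm(death_at=REF + 240.0, alternative_explanation=False)  # day 10
        assert label_infection_related_death(_episode(), adm, [])

    def test_persistent_focus_with_sepsis(self):
        adm = _adm(death_at=REF + 500.0, persistent_focus=True, sepsis_signs=True,
                   alternative_explanation=True)
        assert label_infection_related_death(_episode(), adm, [])

    def test_no_death_is_false(self):
        assert not label_infection_related_death(_episode(), _adm(), [])


class TestCohortInvariants:
    def test_partition_identity(self, small_results):
        """ineffective + optimal + superfluous + other = all episodes, and
        effective = optimal + superfluous + other."""
        out = small_results["outcomes"]
        counts = out["empirical_category"].value_counts()
        total = sum(counts.get(c, 0) for c in (CAT_INEFFECTIVE, CAT_OPTIMAL, CAT_SUPERFLUOUS, CAT_OTHER))
        assert total == len(out)
        n_eff = int(out["empirical_effective"].sum())
        assert n_eff == counts.get(CAT_OPTIMAL, 0) + counts.get(CAT_SUPERFLUOUS, 0) + counts.get(CAT_OTHER, 0)

    def test_event_time_ordering_and_censor_bounds(self, small_results):
        out = small_results["outcomes"]
        both = out[out["eff_event"] & out["opt_event"]]
        assert (both["opt_time"] >= both["eff_time"]).all()
        for col in ("eff_time", "opt_time", "deesc_time", "ivpo_time"):
            assert (out[col] >= 0).all() and (out[col] <= 240.0).all()

    def test_derived_times_match_generator_truth(self, small_cohort, small_results):
        out = small_results["outcomes"]
        truth = small_cohort.truth[small_cohort.truth["included"]]
        merged = truth.merge(out, on="episode_id", suffixes=("_t", ""))
        assert len(merged) == len(truth) == len(out)
        for col in ("eff_time", "opt_time", "deesc_time", "ivpo_time"):
            assert (merged[f"{col}_t"] == merged[col]).all()
        assert (merged["empirical_category_t"] == merged["empirical_category"]).all()
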