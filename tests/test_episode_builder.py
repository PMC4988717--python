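"""Contaminant rule, episode separation, acquisition typing, exclusions."""

import pytest

from bsi_stewardship.domain import ABSENT, Admission, ASTResult, BloodCultureSet, Episode
from bsi_stewardship.episodes import (
    COMMUNITY,
    EXCLUSION_PRECEDENCE,
    HEALTHCARE_ASSOCIATED,
    HOSPITAL_ONSET,
    EpisodeBuildConfig,
    apply_exclusions,
    build_episodes,
    classify_acquisition,
    flag_contaminants,
)

CFG = EpisodeBuildConfig()
CONS = "Coagulase-negative staphylococci"


def _set(set_id, patient, t, organisms, **kw):
    return BloodCultureSet(set_id=set_id, patient_id=patient, ordered_at=t, organisms=organisms, **kw)


def _ast(set_id, organism="Escherichia coli", gram="gram_negative", reported=100.0, **kw):
    return ASTResult(
        isolate_id=f"I-{set_id}", culture_set_id=set_id, organism=organism,
        gram_category=gram, susceptibilities={"CRO": "S"}, reported_at=reported, **kw
    )


def _adm(patient, admitted=0.0, age=60.0, **kw):
    return Admission(patient_id=patient, admitted_at=admitted, age_years=age, **kw)


class TestContaminantRule:
    def test_single_positive_commensal_set_is_contaminant(self):
        sets = [
            _set("a", "p1", 0.0, [CONS], clinically_related_infection=True),
            _set("b", "p1", 2.0, []),
        ]
        flag_contaminants(sets, CFG)
        assert CONS in sets[0].contaminant_organisms
        assert sets[0].pathogens() == []

    def test_two_commensal_sets_with_clinical_infection_are_pathogenic(self):
        sets = [
            _set("a", "p1", 0.0, [CONS]),
            _set("b", "p1", 10.0, [CONS], clinically_related_infection=True),
        ]
        flag_contaminants(sets, CFG)
        assert sets[0].pathogens() == [CONS]
        assert sets[1].pathogens() == [CONS]

    def test_two_commensal_sets_outside_window_are_contaminants(self):
        sets = [
            _set("a", "p1", 0.0, [CONS], clinically_related_infection=True),
            _set("b", "p1", 60.0, [CONS], clinically_related_infection=True),
        ]
        flag_contaminants(sets, CFG)
        assert sets[0].pathogens() == [] and sets[1].pathogens() == []

    def test_noncommensal_single_set_is_pathogen(self):
        sets = [_set("a", "p1", 0.0, ["Escherichia coli"])]
        flag_contaminants(sets, CFG)
        assert sets[0].pathogens() == ["Escherichia coli"]

    def test_unknown_organism_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="unknown organism"):
            flag_contaminants([_set("a", "p1", 0.0, ["Moon dust"])], CFG)


class TestEpisodeSeparation:
    def _build(self, sets, asts):
        flag_contaminants(sets, CFG)
        return build_episodes(sets, {"p1": _adm("p1")}, asts, CFG)

    def test_repeat_culture_within_two_weeks_is_one_episode(self):
        sets = [
            _set("a", "p1", 0.0, ["Escherichia coli"]),
            _set("b", "p1", 120.0, ["Escherichia coli"]),  # day 5
        ]
        eps = self._build(sets, [_ast("a"), _ast("b", reported=200.0)])
        assert len(eps) == 1
        assert eps[0].onset_at == 0.0 and eps[0].reference_at == 100.0

    def test_new_culture_two_weeks_after_onset_is_new_episode(self):
        sets = [
            _set("a", "p1", 0.0, ["Escherichia coli"]),
            _set("b", "p1", 384.0, ["Escherichia coli"]),  # day 16
        ]
        eps = self._build(sets, [_ast("a"), _ast("b", reported=460.0)])
        assert len(eps) == 2

    def test_boundary_at_exactly_two_weeks_starts_new_episode(self):
        sets = [
            _set("a", "p1", 0.0, ["Escherichia coli"]),
            _set("b", "p1", 336.0, ["Escherichia coli"]),
        ]
        eps = self._build(sets, [_ast("a"), _ast("b", reported=400.0)])
        assert len(eps) == 2

    def test_different_infection_flag_splits_within_two_weeks(self):
        sets = [
            _set("a", "p1", 0.0, ["Escherichia coli"]),
            _set("b", "p1", 144.0, ["Escherichia coli"], different_infection=True),  # day 6
        ]
        eps = self._build(sets, [_ast("a"), _ast("b", reported=220.0)])
        assert len(eps) == 2

    def test_sirs_absent_growth_is_not_an_episode(self):
        sets = [_set("a", "p1", 0.0, ["Escherichia coli"], sirs_present=False)]
        eps = self._build(sets, [_ast("a")])
        assert eps == []

    def test_positive_set_without_ast_linkage_errors(self):
        sets = [_set("a", "p1", 0.0, ["Escherichia coli"])]
        flag_contaminants(sets, CFG)
        with pytest.raises(ValueError, match="a"):
            build_episodes(sets, {"p1": _adm("p1")}, [], CFG)

    def test_polymicrobial_set_forms_single_episode(self):
        sets = [_set("a", "p1", 0.0, ["Escherichia coli", "Enterococcus faecalis"])]
        eps = self._build(sets, [_ast("a"), _ast("a", organism="Enterococcus faecalis", gram="gram_positive")])
        assert len(eps) == 1
        assert eps[0].polymicrobial


class TestAcquisition:
    def _episode(self, onset):
        return Episode(
            episode_id="e", patient_id="p1", onset_at=onset, reference_at=onset + 60,
            pathogen="Escherichia coli", gram="gram_negative",
        )

    def test_within_48h_of_ed_without_exposure_is_community(self):
        adm = _adm("p1", admitted=0.0, ed_visit_at=0.0)
        assert classify_acquisition(self._episode(40.0), adm, CFG) == COMMUNITY

    def test_within_48h_with_exposure_is_healthcare_associated(self):
        adm = _adm("p1", healthcare_exposure=True)
        assert classify_acquisition(self._episode(40.0), adm, CFG) == HEALTHCARE_ASSOCIATED

    def test_at_least_48h_after_admission_is_hospital_onset(self):
        assert classify_acquisition(self._episode(60.0), _adm("p1"), CFG) == HOSPITAL_ONSET

    def test_onset_before_admission_errors(self):
        with pytest.raises(ValueError, match="onset precedes"):
            classify_acquisition(self._episode(-1.0), _adm("p1"), CFG)

    @pytest.mark.parametrize("delta", [0.0, 10.0, 47.9, 48.0, 100.0])
    @pytest.mark.parametrize("exposure", [False, True])
    def test_exhaustive_and_mutually_exclusive(self, delta, exposure):
        adm = _adm("p1", healthcare_exposure=exposure)
        got = classify_acquisition(self._episode(delta), adm, CFG)
        if delta >= 48.0:
            assert got == HOSPITAL_ONSET
        else:
            assert got == (HEALTHCARE_ASSOCIATED if exposure else COMMUNITY)


class TestExclusions:
    def _episode(self, **kw):
        defaults = dict(
            episode_id="e", patient_id="p1", onset_at=10.0, reference_at=80.0,
            pathogen="Escherichia coli", gram="gram_negative",
        )
        defaults.update(kw)
        return Episode(**defaults)

    def _run(self, ep, adm):
        return apply_exclusions([ep], {"p1": adm}, CFG)[0]

    def test_early_death_within_24h_of_report(self):
        adm = _adm("p1", death_at=100.0, discharged_at=100.0)
        ep = self._run(self._episode(), adm)
        assert ep.excluded and ep.exclusion_reason == "early_death"

    def test_polymicrobial_excluded(self):
        ep = self._run(self._episode(polymicrobial=True), _adm("p1", discharged_at=500.0))
        assert ep.exclusion_reason == "polymicrobial"

    def test_discharge_before_report_excluded(self):
        ep = self._run(self._episode(), _adm("p1", discharged_at=70.0))
        assert ep.exclusion_reason == "discharged_before_report"

    def test_child_excluded(self):
        ep = self._run(self._episode(), _adm("p1", age=12.0))
        assert ep.exclusion_reason == "age_under_18"

    def test_outpatient_culture_excluded(self):
        ep = self._run(self._episode(), _adm("p1", admitted=50.0))
        assert ep.exclusion_reason == "not_hospitalized_or_ed"

    def test_precedence_age_beats_polymicrobial(self):
        ep = self._run(self._episode(polymicrobial=True), _adm("p1", age=10.0))
        assert ep.exclusion_reason == "age_under_18"

    def test_precedence_order_is_fixed(self):
        assert EXCLUSION_PRECEDENCE == (
            "age_under_18", "not_hospitalized_or_ed", "discharged_before_report",
            "polymicrobial", "early_death", "initiation_month",
        )

    def test_included_episode_gets_acquisition(self):
        ep = self._run(self._episode(), _adm("p1", discharged_at=500.0))
        assert not ep.excluded
        assert ep.acquisition == COMMUNITY


def test_included_count_equals_generated_minus_injected(small_cohort, small_results):
    """Selection accounting: the generator's injected exclusions and noise
    sets are removed, nothing else."""
    truth = small_cohort.truth
    flow = small_results["flow_counts"]
    assert flow["episodes_identified"] == len(truth)
    assert flow["excluded_total"] == int((~truth["included"]).sum())
    n_included = flow["included_pre_program"] + flow["included_program"]
    assert n_included == int(truth["included"].sum())
    noise = small_cohort.noise_sets
    assert flow["culture_sets_contaminant_only"] == int((noise["kind"] == "contaminant").sum())
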