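import pytest

from bsi_stewardship import pipeline, simulate
from bsi_stewardship.domain import KnowledgeBase


def small_spec(seed: int = 7) -> simulate.CohortSpec:
    """A reduced two-period cohort with one of every injected construct."""
    spec = simulate.CohortSpec(seed=seed)
    spec.pre.n_episodes = 60
    spec.post.n_episodes = 60
    spec.injections = simulate.InjectionCounts(
        age_under_18=1,
        not_hospitalized=1,
        discharged_before_report=1,
        polymicrobial=1,
        early_death=1,
        contaminant_sets=2,
        sirs_absent_sets=1,
        repeat_cultures=1,
        recurrence_pairs=1,
        different_infection_pairs=1,
    )
    spec.initiation_month_episodes = 2
    return spec


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    return KnowledgeBase()


@pytest.fixture(scope="session")
def small_cohort() -> simulate.CohortData:
    return simulate.generate_cohort(small_spec())


@pytest.fixture(scope="session")
def small_results(small_cohort, tmp_path_factory):
    records = pipeline.RecordSet(
        small_cohort.cultures,
        small_cohort.asts,
        small_cohort.admissions,
        small_cohort.administrations,
        small_cohort.kb,
    )
    out = tmp_path_factory.mktemp("pipeline")
    return pipeline.run_pipeline(records, pipeline.RunConfig(output_dir=out))
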