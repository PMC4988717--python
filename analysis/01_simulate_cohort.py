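"""Generate the default synthetic two-period BSI cohort and write the raw
record files (blood cultures, AST panels, admissions, administrations) plus
the generator's ground-truth table.

The record files go under scratch/cohort/ (they are inputs for the later
steps, regenerable from the seed); the truth table and a small summary go
under results/analysis/.
"""

from pathlib import Path

from bsi_stewardship import io, simulate

SEED = 1
RECORDS_DIR = Path("scratch/cohort")
RESULTS_DIR = Path("results/analysis")


def main() -> None:
    spec = simulate.CohortSpec(seed=SEED)
    data = simulate.generate_cohort(spec)

    RECORDS_DIR.mkdir(parents=True, exist_ok=True)
    io.write_records_csv(data.cultures, RECORDS_DIR / "cultures.csv")
    io.write_records_csv(data.asts, RECORDS_DIR / "asts.csv")
    io.write_records_csv(list(data.admissions.values()), RECORDS_DIR / "admissions.csv")
    io.write_records_csv(data.administrations, RECORDS_DIR / "administrations.csv")
    data.kb.write_csv(RECORDS_DIR / "knowledge_base.csv")

    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    data.truth.to_csv(RESULTS_DIR / "truth_table.csv", index=False)
    data.noise_sets.to_csv(RESULTS_DIR / "noise_sets.csv", index=False)

    inc = data.truth[data.truth["included"]]
    print(f"generated {len(data.cultures)} culture sets, {len(data.asts)} AST reports,")
    print(f"  {len(data.administrations)} administration records for {len(data.admissions)} patients")
    print(f"episodes: {len(inc)} included "
          f"({(inc['period'] == 'pre_program').sum()} pre / {(inc['period'] == 'program').sum()} program), "
          f"{(~data.truth['included']).sum()} injected exclusions, "
          f"{len(data.noise_sets)} noise sets")
    print("empirical mix (pre): ",
          inc[inc["period"] == "pre_program"]["empirical_category"].value_counts().to_dict())


if __name__ == "__main__":
    main()
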