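"""Classify each included episode's antimicrobial regimen over time: the
empirical category at the reference time and the four time-to-event
outcomes (effective, optimal, de-escalation, IV-to-oral switch) with the
240-hour censoring policy, plus 30-day mortality labels.
"""

from pathlib import Path

from bsi_stewardship import pipeline

RECORDS_DIR = Path("scratch/cohort")
RESULTS_DIR = Path("results/analysis")


def main() -> None:
    records = pipeline.RecordSet.from_dir(RECORDS_DIR, kb_path=RECORDS_DIR / "knowledge_base.csv")
    config = pipeline.RunConfig(output_dir=RESULTS_DIR)
    eps, _ = pipeline.build_stage(records, config)
    outcomes = pipeline.classify_stage(records, eps, config)
    outcomes.to_csv(RESULTS_DIR / "outcomes.csv", index=False)

    for period in ("pre_program", "program"):
        sub = outcomes[outcomes["period"] == period]
        counts = sub["empirical_category"].value_counts().to_dict()
        n_eff = int(sub["empirical_effective"].sum())
        print(f"{period}: n={len(sub)}, empirical {counts}, effective={n_eff}")
        print(f"  30-day mortality {int(sub['death30'].sum())}/{len(sub)}, "
              f"infection-related {int(sub['infection_related_death'].sum())}")


if __name__ == "__main__":
    main()
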