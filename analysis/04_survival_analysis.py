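"""Kaplan-Meier analysis of the four appropriateness outcomes: per-period
curves, landmark proportions with Greenwood confidence intervals, medians
and the two-period log-rank tests.
"""

from pathlib import Path

import pandas as pd

from bsi_stewardship import pipeline

RESULTS_DIR = Path("results/analysis")


def main() -> None:
    outcomes = pd.read_csv(RESULTS_DIR / "outcomes.csv")
    config = pipeline.RunConfig(output_dir=RESULTS_DIR)
    report, curves = pipeline.survival_stage(outcomes, config)
    report.to_csv(RESULTS_DIR / "survival.csv", index=False)
    for (outcome, period), curve in curves.items():
        curve.to_frame().to_csv(RESULTS_DIR / f"km_{outcome}_{period}.csv", index=False)

    for outcome in ("effective", "optimal", "deescalation"):
        sub = report[report["outcome"] == outcome]
        line = " vs ".join(
            f"{row['period']}: {100 * row['prop_24h']:.1f}% at 24 h "
            f"({100 * row['prop_24h_ci_low']:.1f}-{100 * row['prop_24h_ci_high']:.1f})"
            for _, row in sub.iterrows()
        )
        p = sub["logrank_p"].iloc[0]
        print(f"{outcome}: {line}; log-rank p = {p:.2g}")


if __name__ == "__main__":
    main()
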