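"""Program-period subgroup analysis: episodes whose automated consultations
were canceled versus those that went through — log-rank per outcome, 2x2
tests on the reference-time categories, rank-sum on length of stay.
"""

from pathlib import Path

import pandas as pd

from bsi_stewardship import pipeline

RESULTS_DIR = Path("results/analysis")


def main() -> None:
    outcomes = pd.read_csv(RESULTS_DIR / "outcomes.csv")
    post = outcomes[outcomes["period"] == "program"]
    report = pipeline.subgroup_compare(post, "consult_canceled")
    report.to_csv(RESULTS_DIR / "subgroup_canceled.csv", index=False)

    n_canceled = int(post["consult_canceled"].sum())
    print(f"program period: {n_canceled}/{len(post)} consultations canceled "
          f"({100 * n_canceled / len(post):.1f}%)")
    for _, row in report.iterrows():
        if row.get("applicable"):
            print(f"  {row['comparison']}: p = {row['p_value']:.3f}")
        else:
            print(f"  {row['comparison']}: not applicable")


if __name__ == "__main__":
    main()
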