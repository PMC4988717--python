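"""Interrupted time series: monthly proportions on appropriate therapy at
24 and 48 hours, segmented OLS around the program start, Durbin-Watson
autocorrelation diagnostics.
"""

from pathlib import Path

import pandas as pd

from bsi_stewardship import its

RESULTS_DIR = Path("results/analysis")


def main() -> None:
    outcomes = pd.read_csv(RESULTS_DIR / "outcomes.csv")
    report = its.its_report(outcomes)
    report.to_csv(RESULTS_DIR / "its.csv", index=False)
    for _, row in report.iterrows():
        print(
            f"{row['outcome']:>12} @ {row['landmark_h']:>4.0f} h: "
            f"level change {row['level_change']:+.3f} (p = {row['level_change_p']:.3f}), "
            f"trend change {row['trend_change']:+.4f} (p = {row['trend_change_p']:.3f}), "
            f"DW = {row['durbin_watson']:.2f}"
        )


if __name__ == "__main__":
    main()
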