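"""End-to-end orchestration: records -> episodes -> outcomes -> reports.

``run_pipeline`` executes build -> classify -> survival -> ITS -> tables on
an in-memory record set (or one loaded from files) and writes the report
bundle as delimited-text tables. Stages are pure given their inputs: any
intermediate table can be re-fed to resume, and a rerun with the same
inputs produces byte-identical reports. The numbered scripts under
``analysis/`` are thin drivers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import episodes as ep_mod
from . import its as its_mod
from . import survival as surv_mod
from . import tables as tab_mod
from . import therapy as ther_mod
from .domain import Admission, AdministrationRecord, ASTResult, BloodCultureSet, KnowledgeBase
from .io import read_records_csv


@dataclass
class RunConfig:
    output_dir: Path | str = "results/pipeline"
    landmarks_h: tuple[float, ...] = (24.0, 48.0)
    switch_landmarks_h: tuple[float, ...] = (48.0, 96.0, 192.0)  # days 2, 4, 8
    censor_horizon_h: float = 240.0
    build: ep_mod.EpisodeBuildConfig = field(default_factory=ep_mod.EpisodeBuildConfig)

    def __post_init__(self):
        if self.censor_horizon_h <= max(self.landmarks_h):
            raise ValueError("censor horizon must exceed the largest landmark")


@dataclass
class RecordSet:
    cultures: list[BloodCultureSet]
    asts: list[ASTResult]
    admissions: dict[str, Admission]
    administrations: list[AdministrationRecord]
    kb: KnowledgeBase

    @classmethod
    def from_dir(cls, path: Path | str, kb_path: Path | str | None = None) -> "RecordSet":
        path = Path(path)
        admissions = {a.patient_id: a for a in read_records_csv(Admission, path / "admissions.csv")}
        kb = KnowledgeBase.read_csv(kb_path) if kb_path else KnowledgeBase()
        return cls(
            cultures=read_records_csv(BloodCultureSet, path / "cultures.csv"),
            asts=read_records_csv(ASTResult, path / "asts.csv"),
            admissions=admissions,
            administrations=read_records_csv(AdministrationRecord, path / "administrations.csv"),
            kb=kb,
        )


def build_stage(records: RecordSet, config: RunConfig) -> tuple[list, dict]:
    """Contaminant flagging, episode building and exclusion labeling."""
    cultures = ep_mod.flag_contaminants(records.cultures, config.build)
    eps = ep_mod.build_episodes(cultures, records.admissions, records.asts, config.build)
    eps = ep_mod.apply_exclusions(eps, records.admissions, config.build)
    return eps, ep_mod.flow_counts(cultures, eps)


def classify_stage(records: RecordSet, eps: list, config: RunConfig) -> pd.DataFrame:
    asts_by_set = {}
    for ast in records.asts:
        asts_by_set.setdefault(ast.culture_set_id, ast)
    admins_by_patient: dict[str, list] = {}
    for rec in records.administrations:
        admins_by_patient.setdefault(rec.patient_id, []).append(rec)
    return ther_mod.build_outcome_table(
        eps,
        records.admissions,
        asts_by_set,
        admins_by_patient,
        records.cultures,
        records.kb,
        horizon_h=config.censor_horizon_h,
    )


def survival_stage(outcomes: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Per-outcome, per-period KM curves, landmark proportions, medians and
    the two-period log-rank tests."""
    rows = []
    curves = {}
    for outcome, (t_col, e_col, elig_col) in its_mod.OUTCOME_COLUMNS.items():
        df = outcomes if elig_col is None else outcomes[outcomes[elig_col]]
        landmarks = (
            config.switch_landmarks_h if outcome == "ivpo" else config.landmarks_h
        )
        per_period = {}
        for period in ("pre_program", "program"):
            sub = df[df["period"] == period]
            if sub.empty:
                continue
            curve = surv_mod.km_fit(sub[t_col].to_numpy(), sub[e_col].to_numpy())
            per_period[period] = (sub, curve)
            curves[(outcome, period)] = curve
            median, med_ci = surv_mod.km_median(curve)
            row = {
                "outcome": outcome,
                "period": period,
                "n": len(sub),
                "events": int(sub[e_col].sum()),
                "median_h": median,
                "median_ci_low": med_ci[0],
                "median_ci_high": med_ci[1],
            }
            for lm in landmarks:
                p, lo, hi, _ = surv_mod.km_proportion_at(curve, lm)
                row[f"prop_{lm:g}h"] = p
                row[f"prop_{lm:g}h_ci_low"] = lo
                row[f"prop_{lm:g}h_ci_high"] = hi
            rows.append(row)
        if len(per_period) == 2:
            (a, _), (b, _) = per_period["pre_program"], per_period["program"]
            chi2, p = surv_mod.log_rank(
                a[t_col].to_numpy(), a[e_col].to_numpy(),
                b[t_col].to_numpy(), b[e_col].to_numpy(),
            )
            for row in rows:
                if row["outcome"] == outcome:
                    row["logrank_chi2"] = chi2
                    row["logrank_p"] = p
    return pd.DataFrame(rows), curves


BASELINE_BINARY_VARS = [
    ("icu", "binary"),
    ("esbl_flag", "binary"),
    ("empirical_effective", "binary"),
    ("empirical_superfluous", "binary"),
    ("empirical_optimal", "binary"),
    ("death30", "binary"),
    ("infection_related_death", "binary"),
]


def tables_stage(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Two-period baseline comparison (Table 1/2-shaped)."""
    variables = list(BASELINE_BINARY_VARS)
    alive = outcomes[~outcomes["death_outcome"]]
    table = tab_mod.table_one(outcomes, variables, group_col="period")
    if len(alive["period"].unique()) == 2 and alive["los_h"].notna().any():
        los = tab_mod.table_one(alive, [("los_h", "continuous")], group_col="period")
        table = pd.concat([table, los], ignore_index=True)
    return table


def run_pipeline(records: RecordSet, config: RunConfig | None = None) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the episode table, outcome table, survival report,
    ITS report, baseline table and flow counts; each is also written as a
    CSV file under ``config.output_dir``.
    """
    config = config or RunConfig()
    eps, flow = build_stage(records, config)
    outcomes = classify_stage(records, eps, config)
    survival_report, curves = survival_stage(outcomes, config)
    its_report = its_mod.its_report(outcomes, landmarks=config.landmarks_h)
    baseline = tables_stage(outcomes)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    episode_tbl = ep_mod.episode_table(eps)
    episode_tbl.to_csv(out / "episodes.csv", index=False)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    survival_report.to_csv(out / "survival.csv", index=False)
    its_report.to_csv(out / "its.csv", index=False)
    baseline.to_csv(out / "baseline.csv", index=False)
    pd.DataFrame([flow]).to_csv(out / "flow_counts.csv", index=False)
    for (outcome, period), curve in curves.items():
        curve.to_frame().to_csv(out / f"km_{outcome}_{period}.csv", index=False)
    return {
        "episodes": episode_tbl,
        "outcomes": outcomes,
        "survival": survival_report,
        "its": its_report,
        "baseline": baseline,
        "flow_counts": flow,
        "curves": curves,
    }


def subgroup_compare(outcomes: pd.DataFrame, flag: str) -> pd.DataFrame:
    """Generic two-level subgroup report (e.g. canceled vs kept automated
    consultations): log-rank per time-to-event outcome, chi-square/Fisher on
    the reference-time categories, rank-sum on length of stay among
    survivors."""
    levels = sorted(outcomes[flag].dropna().unique())
    rows = []
    if len(levels) != 2:
        for outcome in its_mod.OUTCOME_COLUMNS:
            rows.append({"comparison": f"logrank_{outcome}", "applicable": False})
        rows.append({"comparison": "length_of_stay", "applicable": False})
        return pd.DataFrame(rows)
    g1 = outcomes[outcomes[flag] == levels[1]]  # flag-positive first, as exposed group
    g0 = outcomes[outcomes[flag] == levels[0]]
    for outcome, (t_col, e_col, elig_col) in its_mod.OUTCOME_COLUMNS.items():
        a = g1 if elig_col is None else g1[g1[elig_col]]
        b = g0 if elig_col is None else g0[g0[elig_col]]
        if a.empty or b.empty:
            rows.append({"comparison": f"logrank_{outcome}", "applicable": False})
            continue
        chi2, p = surv_mod.log_rank(
            a[t_col].to_numpy(), a[e_col].to_numpy(),
            b[t_col].to_numpy(), b[e_col].to_numpy(),
        )
        rows.append(
            {"comparison": f"logrank_{outcome}", "applicable": True,
             "statistic": chi2, "p_value": p,
             "n_exposed": len(a), "n_reference": len(b)}
        )
    for col in ("empirical_effective", "empirical_optimal", "empirical_superfluous",
                "prior_consultation", "death30"):
        a_yes, a_no = int(g1[col].sum()), len(g1) - int(g1[col].sum())
        b_yes, b_no = int(g0[col].sum()), len(g0) - int(g0[col].sum())
        test, p = tab_mod.choose_2x2_test([[a_yes, a_no], [b_yes, b_no]])
        rows.append(
            {"comparison": col, "applicable": True, "test": test, "p_value": p,
             "n_exposed": a_yes, "n_reference": b_yes}
        )
    a_los = g1[~g1["death_outcome"]]["los_h"].dropna().to_numpy()
    b_los = g0[~g0["death_outcome"]]["los_h"].dropna().to_numpy()
    if a_los.size and b_los.size:
        stat, p = tab_mod.rank_sum_test(a_los, b_los)
        rows.append(
            {"comparison": "length_of_stay", "applicable": True,
             "statistic": stat, "p_value": p}
        )
    else:
        rows.append({"comparison": "length_of_stay", "applicable": False})
    return pd.DataFrame(rows)
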