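"""Core data types shared by all pipeline stages.

Internally every timestamp is a real number of hours from a single study
origin (a civil datetime); calendar months are derived by attaching the
origin back. Generated and serialized times are snapped to a dyadic
1/1024-hour grid so that interval arithmetic is exact in double precision
and ISO-8601 file round-trips reproduce the in-memory floats bit-exactly.

The clinical booleans (dose/site adequacy, the IV-to-oral clinical-course
flags, the mortality-adjudication flags) are *inputs*: they stand in for
chart review and are never computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import pandas as pd

# --------------------------------------------------------------------------
# Time handling

#: Civil datetime corresponding to hour 0 of the study clock.
STUDY_ORIGIN = datetime(2010, 8, 1, 0, 0, 0)

#: Date the stewardship program started; its calendar month is excluded.
PROGRAM_START = datetime(2011, 8, 19, 0, 0, 0)

#: Calendar month (year, month) excluded around program initiation.
INITIATION_MONTH = (2011, 8)


#: resolution of the generated-time grid, in fractions of an hour. 1/1024 h
#: (about 3.5 s) is a dyadic rational: every grid value, and every sum or
#: difference of grid values, is exactly representable as a double, so
#: pipeline-recomputed intervals equal generator-truth intervals bit for bit,
#: and the microsecond-precision ISO-8601 encoding round-trips exactly.
TIME_GRID = 1024


def snap_to_grid(hours: float) -> float:
    """Round an hour offset to the nearest 1/1024 hour (dyadic grid)."""
    return round(hours * TIME_GRID) / TIME_GRID


def hours_to_datetime(hours: float, origin: datetime = STUDY_ORIGIN) -> datetime:
    return origin + timedelta(microseconds=round(hours * 3_600_000_000.0))


def datetime_to_hours(when: datetime, origin: datetime = STUDY_ORIGIN) -> float:
    return (when - origin).total_seconds() / 3600.0


def month_of(hours: float, origin: datetime = STUDY_ORIGIN) -> str:
    """Calendar month label ``YYYY-MM`` of an hour offset."""
    dt = hours_to_datetime(hours, origin)
    return f"{dt.year:04d}-{dt.month:02d}"


def is_absent(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


ABSENT = float("nan")
OPEN = float("inf")

GRAM_POSITIVE = "gram_positive"
GRAM_NEGATIVE = "gram_negative"
ANAEROBE = "anaerobe"
YEAST = "yeast"
GRAM_CATEGORIES = (GRAM_POSITIVE, GRAM_NEGATIVE, ANAEROBE, YEAST)

IV = "IV"
PO = "PO"

# --------------------------------------------------------------------------
# Organism registry

#: organism -> (gram category, is common skin commensal)
ORGANISMS: dict[str, tuple[str, bool]] = {
    "Escherichia coli": (GRAM_NEGATIVE, False),
    "Klebsiella pneumoniae": (GRAM_NEGATIVE, False),
    "Pseudomonas aeruginosa": (GRAM_NEGATIVE, False),
    "Enterobacter cloacae": (GRAM_NEGATIVE, False),
    "Proteus mirabilis": (GRAM_NEGATIVE, False),
    "Acinetobacter baumannii": (GRAM_NEGATIVE, False),
    "Staphylococcus aureus": (GRAM_POSITIVE, False),
    "Coagulase-negative staphylococci": (GRAM_POSITIVE, True),
    "Corynebacterium species": (GRAM_POSITIVE, True),
    "Streptococcus species": (GRAM_POSITIVE, False),
    "Enterococcus faecalis": (GRAM_POSITIVE, False),
    "Bacteroides fragilis": (ANAEROBE, False),
    "Candida albicans": (YEAST, False),
}


def gram_category(organism: str) -> str:
    try:
        return ORGANISMS[organism][0]
    except KeyError:
        raise ValueError(f"unknown organism category: {organism!r}") from None


def is_commensal(organism: str) -> bool:
    try:
        return ORGANISMS[organism][1]
    except KeyError:
        raise ValueError(f"unknown organism category: {organism!r}") from None


# --------------------------------------------------------------------------
# Antimicrobial knowledge base


@dataclass(frozen=True)
class AntimicrobialAgent:
    """One agent of the formulary.

    ``spectrum_rank`` maps a gram category to a non-negative integer; a higher
    rank means a broader spectrum *within that category* and an absent key
    means the agent is not considered for that category. The two superfluous
    flags mark the designated broad-spectrum agents of interest per gram
    category (piperacillin/tazobactam, ceftazidime, cefepime, carbapenems and
    polymyxin E for gram-negatives; glycopeptides and oxazolidinones for
    gram-positives).
    """

    code: str
    name: str
    agent_class: str
    route: str
    spectrum_rank: dict[str, int]
    superfluous_gram_negative: bool = False
    superfluous_gram_positive: bool = False

    def rank(self, gram: str) -> int | None:
        return self.spectrum_rank.get(gram)

    def superfluous_for(self, gram: str) -> bool:
        if gram == GRAM_NEGATIVE:
            return self.superfluous_gram_negative
        if gram == GRAM_POSITIVE:
            return self.superfluous_gram_positive
        return False  # anaerobes and yeasts have no superfluous list


def _agent(code, name, cls, route, ranks, sgn=False, sgp=False):
    return AntimicrobialAgent(code, name, cls, route, ranks, sgn, sgp)


DEFAULT_AGENTS: tuple[AntimicrobialAgent, ...] = (
    _agent("MEM", "meropenem", "carbapenem", IV, {GRAM_NEGATIVE: 5}, sgn=True),
    _agent("IPM", "imipenem", "carbapenem", IV, {GRAM_NEGATIVE: 5}, sgn=True),
    _agent("TZP", "piperacillin/tazobactam", "penicillin-bli", IV, {GRAM_NEGATIVE: 4}, sgn=True),
    _agent("FEP", "cefepime", "cephalosporin-4g", IV, {GRAM_NEGATIVE: 4}, sgn=True),
    _agent("CAZ", "ceftazidime", "cephalosporin-3g", IV, {GRAM_NEGATIVE: 3}, sgn=True),
    _agent("CST", "polymyxin E", "polymyxin", IV, {GRAM_NEGATIVE: 5}, sgn=True),
    _agent("CRO", "ceftriaxone", "cephalosporin-3g", IV, {GRAM_NEGATIVE: 3}),
    _agent("CIP", "ciprofloxacin", "fluoroquinolone", IV, {GRAM_NEGATIVE: 3}),
    _agent("CIP-PO", "ciprofloxacin (oral)", "fluoroquinolone", PO, {GRAM_NEGATIVE: 3}),
    _agent("GEN", "gentamicin", "aminoglycoside", IV, {GRAM_NEGATIVE: 2, GRAM_POSITIVE: 1}),
    _agent("CFZ", "cefazolin", "cephalosporin-1g", IV, {GRAM_NEGATIVE: 1, GRAM_POSITIVE: 2}),
    _agent("LEX-PO", "cephalexin (oral)", "cephalosporin-1g", PO, {GRAM_NEGATIVE: 1, GRAM_POSITIVE: 2}),
    _agent("VAN", "vancomycin", "glycopeptide", IV, {GRAM_POSITIVE: 4}, sgp=True),
    _agent("TEC", "teicoplanin", "glycopeptide", IV, {GRAM_POSITIVE: 4}, sgp=True),
    _agent("LZD", "linezolid", "oxazolidinone", IV, {GRAM_POSITIVE: 4}, sgp=True),
    _agent("LZD-PO", "linezolid (oral)", "oxazolidinone", PO, {GRAM_POSITIVE: 4}, sgp=True),
    _agent("NAF", "nafcillin", "penicillin", IV, {GRAM_POSITIVE: 1}),
    _agent("AMP", "ampicillin", "penicillin", IV, {GRAM_POSITIVE: 1}),
    _agent("AMX-PO", "amoxicillin (oral)", "penicillin", PO, {GRAM_POSITIVE: 1}),
    _agent("MTZ", "metronidazole", "nitroimidazole", IV, {ANAEROBE: 1}),
    _agent("MTZ-PO", "metronidazole (oral)", "nitroimidazole", PO, {ANAEROBE: 1}),
    _agent("FLU", "fluconazole", "azole", IV, {YEAST: 1}),
    _agent("FLU-PO", "fluconazole (oral)", "azole", PO, {YEAST: 1}),
    _agent("CAS", "caspofungin", "echinocandin", IV, {YEAST: 2}),
)


class KnowledgeBase:
    """Editable agent formulary used by the therapy classifier.

    Ships with a default table; can be round-tripped through a delimited text
    file so hospitals can adapt ranks and flags without code changes.
    """

    def __init__(self, agents: list[AntimicrobialAgent] | tuple[AntimicrobialAgent, ...] = DEFAULT_AGENTS):
        self.agents: dict[str, AntimicrobialAgent] = {a.code: a for a in agents}

    def __getitem__(self, code: str) -> AntimicrobialAgent:
        try:
            return self.agents[code]
        except KeyError:
            raise KeyError(f"agent code not in knowledge base: {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.agents

    def agents_in_category(self, gram: str) -> list[AntimicrobialAgent]:
        return [a for a in self.agents.values() if a.rank(gram) is not None]

    def has_nonsuperfluous_active(self, gram: str, susceptibilities: dict[str, str]) -> bool:
        """True if the pathogen is susceptible (S) to at least one
        non-superfluous agent of its gram category in the formulary."""
        for agent in self.agents_in_category(gram):
            if agent.superfluous_for(gram):
                continue
            if susceptibilities.get(agent.code) == "S":
                return True
        return False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.agents.values():
            row = {
                "code": a.code,
                "name": a.name,
                "agent_class": a.agent_class,
                "route": a.route,
                "superfluous_gram_negative": a.superfluous_gram_negative,
                "superfluous_gram_positive": a.superfluous_gram_positive,
            }
            for gram in GRAM_CATEGORIES:
                r = a.rank(gram)
                row[f"rank_{gram}"] = "" if r is None else r
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "KnowledgeBase":
        agents = []
        for _, row in frame.iterrows():
            ranks = {}
            for gram in GRAM_CATEGORIES:
                v = row.get(f"rank_{gram}", "")
                if v != "" and not (isinstance(v, float) and math.isnan(v)):
                    ranks[gram] = int(v)
            agents.append(
                AntimicrobialAgent(
                    code=str(row["code"]),
                    name=str(row["name"]),
                    agent_class=str(row["agent_class"]),
                    route=str(row["route"]),
                    spectrum_rank=ranks,
                    superfluous_gram_negative=bool(row["superfluous_gram_negative"]),
                    superfluous_gram_positive=bool(row["superfluous_gram_positive"]),
                )
            )
        return cls(agents)

    @classmethod
    def read_csv(cls, path) -> "KnowledgeBase":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


# --------------------------------------------------------------------------
# Clinical step flags


@dataclass(frozen=True)
class StepFlag:
    """Monotone boolean step function of time: false before ``true_from``,
    true from then on (``inf`` = never true)."""

    true_from: float = OPEN

    def at(self, t: float) -> bool:
        return t >= self.true_from


# --------------------------------------------------------------------------
# Record types


@dataclass
class BloodCultureSet:
    """One ordered blood-culture set; empty organism list = negative."""

    set_id: str
    patient_id: str
    ordered_at: float
    organisms: list[str] = field(default_factory=list)
    sirs_present: bool = True
    clinically_related_infection: bool = False
    different_infection: bool = False
    infection_site: str = "unknown"
    contaminant_organisms: set[str] = field(default_factory=set)

    def pathogens(self) -> list[str]:
        return [o for o in self.organisms if o not in self.contaminant_organisms]


@dataclass
class ASTResult:
    """Organism identification + susceptibility panel for one culture set.

    ``reported_at`` is the reference time of the episode anchored on this
    isolate. The automated-consultation process flags ride on the report.
    """

    isolate_id: str
    culture_set_id: str
    organism: str
    gram_category: str
    susceptibilities: dict[str, str]
    reported_at: float
    esbl_flag: bool = False
    commensal_organism: bool = False
    consult_canceled: bool = False
    prior_consultation: bool = False


@dataclass
class AdministrationRecord:
    """One agent's administration timeline for a patient.

    ``stop_at`` records the first *missed* scheduled slot when an order is
    discontinued (the study convention imputes discontinuation at the next
    scheduled administration after the last given dose); ``inf`` = still
    running. ``scheduled_times`` are the given doses, strictly increasing and
    within ``[start_at, stop_at]``.
    """

    patient_id: str
    agent_code: str
    route: str
    start_at: float
    stop_at: float = OPEN
    scheduled_times: list[float] = field(default_factory=list)
    dose_adequate: bool = True
    site_adequate: bool = True


@dataclass
class Admission:
    patient_id: str
    admitted_at: float
    age_years: float
    ed_visit_at: float = ABSENT
    discharged_at: float = OPEN
    death_at: float = ABSENT
    icu_at_onset: bool = False
    healthcare_exposure: bool = False
    oral_intake_normal: StepFlag = field(default_factory=StepFlag)
    afebrile: StepFlag = field(default_factory=StepFlag)
    inflammatory_markers_decreasing: StepFlag = field(default_factory=StepFlag)
    symptoms_improving: StepFlag = field(default_factory=StepFlag)
    iv_only_indication: bool = False
    # mortality-adjudication chart-review stand-ins
    persistent_focus: bool = False
    sepsis_signs: bool = False
    alternative_explanation: bool = False


@dataclass
class Episode:
    """One BSI event, anchored at onset (initial culture order) and the
    reference time (ID/AST report of the index isolate)."""

    episode_id: str
    patient_id: str
    onset_at: float
    reference_at: float
    pathogen: str
    gram: str
    acquisition: str = "unclassified"
    period: str = "pre_program"
    excluded: bool = False
    exclusion_reason: str = ""
    infection_site: str = "unknown"
    index_set_id: str = ""
    polymicrobial: bool = False
    esbl_flag: bool = False
    consult_canceled: bool = False
    prior_consultation: bool = False
    death_at: float = ABSENT
    discharged_at: float = OPEN
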