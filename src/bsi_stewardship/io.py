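"""File formats for the record entities.

Each entity has a delimited-text (CSV) representation and a record-per-line
JSON representation. Timestamps are ISO-8601 at microsecond precision in
files and hours from the study origin in memory; because generated times
sit on the dyadic 1/1024-hour grid the conversion round-trips bit-exactly. Absent timestamps
are empty cells; open intervals (still running / not discharged) are the
literal ``open``.
"""

from __future__ import annotations

import json
import math
from typing import Any, Callable

import pandas as pd

from .domain import (
    ABSENT,
    OPEN,
    STUDY_ORIGIN,
    Admission,
    AdministrationRecord,
    ASTResult,
    BloodCultureSet,
    StepFlag,
    datetime_to_hours,
    hours_to_datetime,
)

_ISO = "%Y-%m-%dT%H:%M:%S.%f"


def _fmt_ts(hours: float) -> str:
    if isinstance(hours, float) and math.isnan(hours):
        return ""
    if hours == OPEN:
        return "open"
    return hours_to_datetime(hours, STUDY_ORIGIN).strftime(_ISO)


def _parse_ts(text: str) -> float:
    text = (text or "").strip()
    if not text:
        return ABSENT
    if text == "open":
        return OPEN
    from datetime import datetime

    return datetime_to_hours(datetime.strptime(text, _ISO), STUDY_ORIGIN)


def _fmt_ts_list(hours: list[float]) -> str:
    return ";".join(_fmt_ts(h) for h in hours)


def _parse_ts_list(text: str) -> list[float]:
    text = (text or "").strip()
    if not text:
        return []
    return [_parse_ts(part) for part in text.split(";")]


def _fmt_str_list(items: list[str]) -> str:
    return ";".join(items)


def _parse_str_list(text: str) -> list[str]:
    text = (text or "").strip()
    return [s for s in text.split(";") if s] if text else []


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(text: str) -> bool:
    return str(text).strip().lower() in ("true", "1", "yes")


def _fmt_map(d: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(d.items()))


def _parse_map(text: str) -> dict[str, str]:
    text = (text or "").strip()
    out: dict[str, str] = {}
    if not text:
        return out
    for part in text.split(";"):
        k, _, v = part.partition("=")
        out[k] = v
    return out


# (column, to_text, from_text, attribute-or-None) per entity; attribute None
# means same name as column.
_Codec = tuple[str, Callable[[Any], str], Callable[[str], Any]]

_CULTURE_CODECS: list[_Codec] = [
    ("set_id", str, str),
    ("patient_id", str, str),
    ("ordered_at", _fmt_ts, _parse_ts),
    ("organisms", _fmt_str_list, _parse_str_list),
    ("sirs_present", _fmt_bool, _parse_bool),
    ("clinically_related_infection", _fmt_bool, _parse_bool),
    ("different_infection", _fmt_bool, _parse_bool),
    ("infection_site", str, str),
]

_AST_CODECS: list[_Codec] = [
    ("isolate_id", str, str),
    ("culture_set_id", str, str),
    ("organism", str, str),
    ("gram_category", str, str),
    ("susceptibilities", _fmt_map, _parse_map),
    ("reported_at", _fmt_ts, _parse_ts),
    ("esbl_flag", _fmt_bool, _parse_bool),
    ("commensal_organism", _fmt_bool, _parse_bool),
    ("consult_canceled", _fmt_bool, _parse_bool),
    ("prior_consultation", _fmt_bool, _parse_bool),
]

_ADMIN_CODECS: list[_Codec] = [
    ("patient_id", str, str),
    ("agent_code", str, str),
    ("route", str, str),
    ("start_at", _fmt_ts, _parse_ts),
    ("stop_at", _fmt_ts, _parse_ts),
    ("scheduled_times", _fmt_ts_list, _parse_ts_list),
    ("dose_adequate", _fmt_bool, _parse_bool),
    ("site_adequate", _fmt_bool, _parse_bool),
]


def _fmt_flag(f: StepFlag) -> str:
    return _fmt_ts(f.true_from) if f.true_from != OPEN else "open"


def _parse_flag(text: str) -> StepFlag:
    return StepFlag(_parse_ts(text))


_ADMISSION_CODECS: list[_Codec] = [
    ("patient_id", str, str),
    ("admitted_at", _fmt_ts, _parse_ts),
    ("age_years", lambda x: repr(float(x)), float),
    ("ed_visit_at", _fmt_ts, _parse_ts),
    ("discharged_at", _fmt_ts, _parse_ts),
    ("death_at", _fmt_ts, _parse_ts),
    ("icu_at_onset", _fmt_bool, _parse_bool),
    ("healthcare_exposure", _fmt_bool, _parse_bool),
    ("oral_intake_normal", _fmt_flag, _parse_flag),
    ("afebrile", _fmt_flag, _parse_flag),
    ("inflammatory_markers_decreasing", _fmt_flag, _parse_flag),
    ("symptoms_improving", _fmt_flag, _parse_flag),
    ("iv_only_indication", _fmt_bool, _parse_bool),
    ("persistent_focus", _fmt_bool, _parse_bool),
    ("sepsis_signs", _fmt_bool, _parse_bool),
    ("alternative_explanation", _fmt_bool, _parse_bool),
]

_ENTITY_CODECS = {
    BloodCultureSet: _CULTURE_CODECS,
    ASTResult: _AST_CODECS,
    AdministrationRecord: _ADMIN_CODECS,
    Admission: _ADMISSION_CODECS,
}


def _to_row(record, codecs: list[_Codec]) -> dict[str, str]:
    return {col: enc(getattr(record, col)) for col, enc, _ in codecs}


def _from_row(cls, row: dict[str, Any], codecs: list[_Codec]):
    kwargs = {col: dec("" if row.get(col) is None else str(row[col])) for col, _, dec in codecs}
    return cls(**kwargs)


def write_records_csv(records: list, path) -> None:
    """Write a homogeneous list of entity records to a delimited-text file."""
    if not records:
        raise ValueError("cannot infer entity schema from an empty record list")
    codecs = _ENTITY_CODECS[type(records[0])]
    frame = pd.DataFrame([_to_row(r, codecs) for r in records])
    frame.to_csv(path, index=False)


def read_records_csv(cls, path) -> list:
    codecs = _ENTITY_CODECS[cls]
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [_from_row(cls, row, codecs) for row in frame.to_dict("records")]


def write_records_jsonl(records: list, path) -> None:
    """Record-per-line JSON dialect: same field encodings as the CSV form."""
    if not records:
        raise ValueError("cannot infer entity schema from an empty record list")
    codecs = _ENTITY_CODECS[type(records[0])]
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(_to_row(r, codecs)) + "\n")


def read_records_jsonl(cls, path) -> list:
    codecs = _ENTITY_CODECS[cls]
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(_from_row(cls, json.loads(line), codecs))
    return out
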