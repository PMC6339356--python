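"""Readers and writers for the patient-table CSV schema and run manifests.

The interchange format is a plain UTF-8 CSV with a fixed header.  Empty
cells mean *missing*; dates are ISO-8601; platelets are absolute counts per
microlitre (a ``x10^3/uL``-style unit suffix on the header is recognised
and converted).  Malformed rows are collected into a row-level error report
with line numbers; parsing continues past them.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .records import LAB_ANALYTES, LabPanel, PatientRecord

__all__ = [
    "COLUMNS",
    "read_patient_table",
    "records_to_frame",
    "frame_to_records",
    "write_patient_table",
    "write_manifest",
    "file_digest",
    "RowError",
]

COLUMNS = [
    "patient_id", "sex", "age_years", "kps", "ecog", "primary_site",
    "visceral", "prior_chemo", "multiple_bone_mets",
    "crp", "ldh", "albumin", "platelets", "calcium", "bilirubin",
    "lab_date", "rt_start", "survival_months", "event",
]

_SEX_ALIASES = {
    "m": "male", "male": "male", "man": "male", "men": "male",
    "f": "female", "female": "female", "woman": "female", "women": "female",
}
_EVENT_ALIASES = {
    "died": "died", "dead": "died", "death": "died", "deceased": "died", "1": "died",
    "censored": "censored", "alive": "censored", "0": "censored",
}
_VISCERAL_ALIASES = {
    "none": "none", "no": "none", "nodular": "nodular",
    "disseminated": "disseminated",
}
_BOOL_ALIASES = {
    "yes": True, "y": True, "true": True, "1": True,
    "no": False, "n": False, "false": False, "0": False,
}

# Multipliers for recognised unit suffixes on numeric column headers,
# e.g. "platelets (x10^3/uL)".  Values convert to the canonical unit.
_UNIT_FACTORS = {
    "platelets": {
        "/ul": 1.0,
        "x10^3/ul": 1000.0,
        "10^3/ul": 1000.0,
        "x10^9/l": 1000.0,
        "10^9/l": 1000.0,
    },
}

_HEADER_UNIT_RE = re.compile(r"^(?P<name>[a-z_]+)\s*\((?P<unit>[^)]+)\)$")


@dataclass
class RowError:
    line: int
    patient_id: Optional[str]
    message: str


def _parse_header(raw_columns) -> tuple[list, dict]:
    """Resolve header names, extracting unit suffixes where recognised."""
    names, factors = [], {}
    for raw in raw_columns:
        cell = str(raw).strip()
        m = _HEADER_UNIT_RE.match(cell.lower())
        if m:
            name, unit = m.group("name"), m.group("unit").strip().lower()
            table = _UNIT_FACTORS.get(name)
            if table is None or unit not in table:
                raise ValueError(f"unsupported unit {unit!r} for column {name!r}")
            factors[name] = table[unit]
            names.append(name)
        else:
            names.append(cell.lower())
    unknown = [n for n in names if n not in COLUMNS]
    if unknown:
        raise ValueError(f"unknown column(s): {unknown}")
    missing = [n for n in COLUMNS if n not in names]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    return names, factors


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""


def _opt_float(value, factor=1.0):
    return None if _blank(value) else float(value) * factor

def _opt_int(value):
    return None if _blank(value) else int(float(value))

def _opt_date(value):
    return None if _blank(value) else _dt.date.fromisoformat(str(value).strip())

def _opt_alias(value, table, what):
    if _blank(value):
        return None
    key = str(value).strip().lower()
    if key not in table:
        raise ValueError(f"unrecognised {what} value {value!r}")
    return table[key]


def _row_to_record(row: dict, factors: dict) -> PatientRecord:
    labs = LabPanel(
        crp=_opt_float(row["crp"]),
        ldh=_opt_float(row["ldh"]),
        albumin=_opt_float(row["albumin"]),
        platelets=_opt_float(row["platelets"], factors.get("platelets", 1.0)),
        calcium=_opt_float(row["calcium"]),
        bilirubin=_opt_float(row["bilirubin"]),
        panel_date=_opt_date(row["lab_date"]),
    )
    event = _opt_alias(row["event"], _EVENT_ALIASES, "event")
    if event is None:
        raise ValueError("event is required")
    if _blank(row["survival_months"]):
        raise ValueError("survival_months is required")
    return PatientRecord(
        patient_id=str(row["patient_id"]).strip(),
        sex=_opt_alias(row["sex"], _SEX_ALIASES, "sex"),
        age_years=_opt_int(row["age_years"]),
        kps=_opt_int(row["kps"]),
        ecog=_opt_int(row["ecog"]),
        primary_site=None if _blank(row["primary_site"]) else str(row["primary_site"]).strip(),
        visceral=_opt_alias(row["visceral"], _VISCERAL_ALIASES, "visceral"),
        prior_chemo=_opt_alias(row["prior_chemo"], _BOOL_ALIASES, "prior_chemo"),
        multiple_bone_mets=_opt_alias(
            row["multiple_bone_mets"], _BOOL_ALIASES, "multiple_bone_mets"
        ),
        labs=labs,
        rt_start=_opt_date(row["rt_start"]),
        survival_months=float(row["survival_months"]),
        event=event,
    )


def read_patient_table(path) -> tuple[list, list]:
    """Read a patient CSV into typed records.

    Returns ``(records, errors)`` where ``errors`` is a list of
    :class:`RowError` for rows that failed to parse (the run continues past
    them).  An unknown or missing column raises immediately.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    names, factors = _parse_header(raw.columns)
    raw.columns = names
    records, errors = [], []
    for i, row in enumerate(raw.to_dict(orient="records")):
        line = i + 2  # 1-based, after the header
        try:
            records.append(_row_to_record(row, factors))
        except (ValueError, KeyError) as exc:
            errors.append(RowError(line, row.get("patient_id") or None, str(exc)))
    return records, errors


def frame_to_records(df: pd.DataFrame) -> list:
    """Typed records from an in-memory frame in the CSV schema."""
    names, factors = _parse_header(df.columns)
    df = df.copy()
    df.columns = names
    records = []
    for i, row in enumerate(df.to_dict(orient="records")):
        records.append(_row_to_record(row, factors))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Inverse of :func:`frame_to_records`; empty cells encode missingness."""
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "sex": r.sex,
            "age_years": r.age_years,
            "kps": r.kps,
            "ecog": r.ecog,
            "primary_site": r.primary_site,
            "visceral": r.visceral,
            "prior_chemo": None if r.prior_chemo is None else ("yes" if r.prior_chemo else "no"),
            "multiple_bone_mets": None if r.multiple_bone_mets is None
            else ("yes" if r.multiple_bone_mets else "no"),
            **{a: r.labs.value(a) for a in LAB_ANALYTES},
            "lab_date": None if r.labs.panel_date is None else r.labs.panel_date.isoformat(),
            "rt_start": None if r.rt_start is None else r.rt_start.isoformat(),
            "survival_months": r.survival_months,
            "event": r.event,
        })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_patient_table(df_or_records, path) -> None:
    df = (
        df_or_records
        if isinstance(df_or_records, pd.DataFrame)
        else records_to_frame(df_or_records)
    )
    df.to_csv(path, index=False)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path, *, seed, config_digest: str, input_digest: str, outputs,
    tool_version: str,
) -> dict:
    """Write the run manifest: provenance for one CLI invocation."""
    manifest = {
        "tool_version": tool_version,
        "seed": seed,
        "config_digest": config_digest,
        "input_digest": input_digest,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "outputs": {str(Path(p).name): file_digest(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
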