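"""Cohort I/O: read and write tables of MNCD records as CSV or JSON.

CSV schema (fixed column names, one column per sub-axis)::

    patient_id, years_from_onset,
    m_fluct, m_dysk, m_axial, m_tremor,
    n_neuropsych, n_autonomic, n_sleep_fatigue, n_pain_sensory,
    cognition, dependency

JSON files carry an array of objects with the same field names.  Unknown
columns are preserved on round-trip but otherwise ignored.  Derived columns
(``notation``, ``M``, ``N``, ``stage``, ``table3_conformant``) can be
appended on write; on read they are never trusted — they are recomputed and
any mismatch is reported as a warning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import MNCDRecord, MotorFlags, NonMotorFlags, validate
from .notation import format_notation
from .staging import stage as derive_stage

__all__ = ["CohortTable", "read_cohort", "write_cohort", "SchemaError", "DuplicateVisitError",
           "CSV_COLUMNS", "DERIVED_COLUMNS"]

logger = logging.getLogger(__name__)

CSV_COLUMNS = (
    "patient_id",
    "years_from_onset",
    "m_fluct",
    "m_dysk",
    "m_axial",
    "m_tremor",
    "n_neuropsych",
    "n_autonomic",
    "n_sleep_fatigue",
    "n_pain_sensory",
    "cognition",
    "dependency",
)

DERIVED_COLUMNS = ("notation", "M", "N", "stage", "table3_conformant")

_FLAG_COLUMNS = CSV_COLUMNS[2:10]
_LEVEL_COLUMNS = ("cognition", "dependency")


class SchemaError(ValueError):
    """A cohort file violates the schema; the message names row and column."""


class DuplicateVisitError(ValueError):
    """Two rows share the same (patient_id, years_from_onset) pair."""


@dataclass
class CohortTable:
    """An ordered collection of per-visit records, one row per visit.

    Every row carries ``patient_id`` and ``years_from_onset``; the
    (patient, time) pairs are unique, so rows within a patient sort into a
    well-defined trajectory.  ``extras`` preserves unknown input columns
    (row-aligned) across a round-trip.
    """

    rows: list[MNCDRecord] = field(default_factory=list)
    extras: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, float]] = set()
        for r in self.rows:
            if r.patient_id is None or r.years_from_onset is None:
                raise SchemaError("cohort rows require patient_id and years_from_onset")
            key = (r.patient_id, r.years_from_onset)
            if key in seen:
                raise DuplicateVisitError(f"duplicate visit for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def patients(self) -> list[str]:
        out: list[str] = []
        for r in self.rows:
            if r.patient_id not in out:
                out.append(r.patient_id)
        return out

    def patient_rows(self, patient_id: str) -> list[MNCDRecord]:
        """A patient's visits sorted by time from onset."""
        rows = [r for r in self.rows if r.patient_id == patient_id]
        return sorted(rows, key=lambda r: r.years_from_onset)

    def to_frame(self, with_derived: bool = False) -> pd.DataFrame:
        data: dict[str, list] = {c: [] for c in CSV_COLUMNS}
        for r in self.rows:
            mt, nt = r.motor.as_tuple(), r.nonmotor.as_tuple()
            data["patient_id"].append(r.patient_id)
            data["years_from_onset"].append(r.years_from_onset)
            for col, v in zip(_FLAG_COLUMNS, mt + nt):
                data[col].append(v)
            data["cognition"].append(r.cognition)
            data["dependency"].append(r.dependency)
        frame = pd.DataFrame(data)
        if with_derived:
            staged = [derive_stage(r) for r in self.rows]
            frame["notation"] = [format_notation(r) for r in self.rows]
            frame["M"] = [sum(r.motor.as_tuple()) for r in self.rows]
            frame["N"] = [sum(r.nonmotor.as_tuple()) for r in self.rows]
            frame["stage"] = [s.stage for s in staged]
            frame["table3_conformant"] = [s.table3_conformant for s in staged]
        if self.extras is not None and len(self.extras) == len(frame):
            for col in self.extras.columns:
                if col not in frame.columns:
                    frame[col] = self.extras[col].to_numpy()
        return frame


def _coerce_cell(row_idx: int, col: str, value) -> int:
    try:
        if isinstance(value, str):
            value = value.strip()
        f = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row_idx}, column {col!r}: {value!r} is not numeric") from None
    if math.isnan(f) or f != int(f):
        raise SchemaError(f"row {row_idx}, column {col!r}: {value!r} is not an integer")
    return int(f)


def _row_to_record(row_idx: int, row: dict) -> MNCDRecord:
    for col in CSV_COLUMNS:
        if col not in row or (isinstance(row[col], float) and math.isnan(row[col])):
            raise SchemaError(f"row {row_idx}: missing column {col!r}")
    flags = {}
    for col in _FLAG_COLUMNS + _LEVEL_COLUMNS:
        v = _coerce_cell(row_idx, col, row[col])
        hi = 1 if col in _FLAG_COLUMNS else 2
        if not 0 <= v <= hi:
            raise SchemaError(f"row {row_idx}, column {col!r}: {v} out of range 0..{hi}")
        flags[col] = v
    try:
        years = float(row["years_from_onset"])
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row_idx}, column 'years_from_onset': {row['years_from_onset']!r} is not numeric"
        ) from None
    if years < 0:
        raise SchemaError(f"row {row_idx}, column 'years_from_onset': {years} is negative")
    return MNCDRecord(
        motor=MotorFlags(flags["m_fluct"], flags["m_dysk"], flags["m_axial"], flags["m_tremor"]),
        nonmotor=NonMotorFlags(
            flags["n_neuropsych"],
            flags["n_autonomic"],
            flags["n_sleep_fatigue"],
            flags["n_pain_sensory"],
        ),
        cognition=flags["cognition"],
        dependency=flags["dependency"],
        years_from_onset=years,
        patient_id=str(row["patient_id"]),
    )


def _check_derived(frame: pd.DataFrame, rows: list[MNCDRecord], path) -> None:
    """Recompute any derived columns present in the input and warn on mismatch."""
    if "stage" in frame.columns:
        for i, r in enumerate(rows):
            stored = frame["stage"].iloc[i]
            try:
                stored = int(stored)
            except (TypeError, ValueError):
                continue
            actual = derive_stage(r).stage
            if stored != actual:
                logger.warning(
                    "%s row %d: stored stage %s disagrees with recomputed stage %d; "
                    "derived columns are not authoritative",
                    path, i, stored, actual,
                )
    if "notation" in frame.columns:
        for i, r in enumerate(rows):
            stored = frame["notation"].iloc[i]
            if isinstance(stored, str) and stored.strip() and stored.strip() != format_notation(r):
                logger.warning(
                    "%s row %d: stored notation %r disagrees with recomputed %r",
                    path, i, stored, format_notation(r),
                )


def read_cohort(path, format: Optional[str] = None) -> CohortTable:
    """Read a cohort from CSV or JSON; format inferred from the suffix if omitted.

    Every row must pass structural validation with no ERROR issues;
    WARNING issues (e.g. dementia recorded with full independence) are
    logged and kept.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.read_csv(path, dtype={"patient_id": str})
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if not isinstance(payload, list):
            raise SchemaError(f"{path}: JSON cohort must be an array of record objects")
        frame = pd.DataFrame(payload)
        if frame.empty:
            frame = pd.DataFrame(columns=list(CSV_COLUMNS))
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")

    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing and not frame.empty:
        raise SchemaError(f"{path}: missing columns {missing}")

    rows: list[MNCDRecord] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        if not frame.empty:
            rec = _row_to_record(i, row)
            for issue in validate(rec):
                if issue.is_error():
                    raise SchemaError(f"{path} row {i}: {issue.message}")
                logger.warning("%s row %d: %s", path, i, issue.message)
            rows.append(rec)

    _check_derived(frame, rows, path)
    extra_cols = [c for c in frame.columns if c not in CSV_COLUMNS and c not in DERIVED_COLUMNS]
    extras = frame[extra_cols].copy() if extra_cols else None
    return CohortTable(rows=rows, extras=extras)


def write_cohort(cohort: CohortTable, path, format: Optional[str] = None,
                 with_derived: bool = False) -> None:
    """Write a cohort to CSV or JSON; deterministic byte output for fixed input."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    frame = cohort.to_frame(with_derived=with_derived)
    try:
        if fmt == "csv":
            frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        elif fmt == "json":
            records = frame.to_dict(orient="records")
            for rec in records:  # JSON has a real bool type
                if "table3_conformant" in rec:
                    rec["table3_conformant"] = bool(rec["table3_conformant"])
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(records, fh, indent=2, sort_keys=False)
                fh.write("\n")
        else:
            raise ValueError(f"unknown cohort format {fmt!r}")
    except OSError as exc:
        raise OSError(f"writing cohort to {path}: {exc}") from exc
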