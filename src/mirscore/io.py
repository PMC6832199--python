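"""Cohort CSV round-tripping with row-level validation.

Schema (fixed column order, UTF-8, LF line endings, '.' decimal point):

    patient_id, age, sepsis, icu_death, icu_los, overall_event,
    followup_time, miR-122, miR-133a, miR-143, miR-150, miR-155,
    miR-192, miR-223

Booleans are encoded 0/1; times are days.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from .cohort import MARKERS, CohortRecord
from .errors import SchemaError

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sepsis",
    "icu_death",
    "icu_los",
    "overall_event",
    "followup_time",
) + MARKERS

CONTROL_COLUMNS = ("patient_id", "age") + MARKERS


def _parse_bool(text: str, row: int, column: str) -> bool:
    if text == "0":
        return False
    if text == "1":
        return True
    raise SchemaError(f"row {row}: column {column} must be 0 or 1, got {text!r}")


def _parse_float(text: str, row: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise SchemaError(
            f"row {row}: column {column} is not a number: {text!r}"
        ) from None


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read and validate a cohort CSV; errors carry the 1-based data row."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: missing header") from None
        if tuple(header) != COHORT_COLUMNS:
            raise SchemaError(
                f"bad header: expected {list(COHORT_COLUMNS)}, got {header}"
            )
        records = []
        for i, fields in enumerate(reader, start=1):
            if len(fields) != len(COHORT_COLUMNS):
                raise SchemaError(
                    f"row {i}: expected {len(COHORT_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(COHORT_COLUMNS, fields))
            try:
                record = CohortRecord(
                    patient_id=row["patient_id"],
                    age=_parse_float(row["age"], i, "age"),
                    sepsis=_parse_bool(row["sepsis"], i, "sepsis"),
                    icu_death=_parse_bool(row["icu_death"], i, "icu_death"),
                    icu_los=_parse_float(row["icu_los"], i, "icu_los"),
                    overall_event=_parse_bool(
                        row["overall_event"], i, "overall_event"
                    ),
                    followup_time=_parse_float(
                        row["followup_time"], i, "followup_time"
                    ),
                    markers={
                        m: _parse_float(row[m], i, m) for m in MARKERS
                    },
                )
            except SchemaError as exc:
                if str(exc).startswith("row "):
                    raise
                raise SchemaError(f"row {i}: {exc}") from None
            records.append(record)
    return records


def write_cohort(cohort: Sequence[CohortRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.patient_id,
                    repr(r.age),
                    int(r.sepsis),
                    int(r.icu_death),
                    repr(r.icu_los),
                    int(r.overall_event),
                    repr(r.followup_time),
                ]
                + [repr(r.markers[m]) for m in MARKERS]
            )


def read_controls(path: str | Path) -> list[dict]:
    """Read a control panel CSV (cohort schema minus outcome columns)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty control file: missing header") from None
        if tuple(header) != CONTROL_COLUMNS:
            raise SchemaError(
                f"bad control header: expected {list(CONTROL_COLUMNS)}, "
                f"got {header}"
            )
        rows = []
        for i, fields in enumerate(reader, start=1):
            if len(fields) != len(CONTROL_COLUMNS):
                raise SchemaError(f"row {i}: wrong field count")
            row = dict(zip(CONTROL_COLUMNS, fields))
            parsed: dict = {"patient_id": row["patient_id"]}
            parsed["age"] = _parse_float(row["age"], i, "age")
            for m in MARKERS:
                level = _parse_float(row[m], i, m)
                if not level > 0:
                    raise SchemaError(f"row {i}: marker {m} must be > 0")
                parsed[m] = level
            rows.append(parsed)
    return rows


def write_controls(rows: Sequence[dict], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CONTROL_COLUMNS)
        for r in rows:
            writer.writerow(
                [r["patient_id"], repr(r["age"])] + [repr(r[m]) for m in MARKERS]
            )
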