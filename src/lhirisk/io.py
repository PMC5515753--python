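"""Cohort table I/O.

The on-disk format is a UTF-8 CSV with a header row, one patient per row.
Booleans are 0/1, territories are a semicolon-joined subset of
``deep;superior;posterior``, and a missing day-5 NIHSS is an empty field.
Synthetic and real cohorts share this schema, so they are interchangeable
everywhere downstream.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .records import BOOL_FIELDS, PatientRecord, RecordValidationError

__all__ = [
    "COHORT_COLUMNS",
    "SchemaError",
    "RowError",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
]

COHORT_COLUMNS = [
    "patient_id", "age", "sex",
    "chf", "hypertension", "diabetes", "prior_stroke_or_tia",
    "atrial_fibrillation", "smoking", "hypercholesterolemia",
    "coronary_artery_disease",
    "nihss_admission", "nihss_day5",
    "hypodensity_gt_one_third", "hmcas", "brain_edema",
    "territories", "mca_fraction",
    "died_in_hospital", "stroke_related_death", "thrombolysis", "craniectomy",
]


class SchemaError(ValueError):
    """The cohort file is missing required columns."""


class RowError:
    """A row that failed validation: row number (1-based, excluding header) and details."""

    def __init__(self, row: int, errors: list[tuple[str, str]]):
        self.row = row
        self.errors = errors

    def __repr__(self):
        detail = "; ".join(f"{f}: {m}" for f, m in self.errors)
        return f"RowError(row={self.row}, {detail})"


def _row_to_record(row: pd.Series) -> PatientRecord:
    terrs = row["territories"]
    if isinstance(terrs, str):
        terrs = frozenset(t for t in terrs.split(";") if t)
    elif terrs is None or (isinstance(terrs, float) and np.isnan(terrs)):
        terrs = frozenset()
    day5 = row["nihss_day5"]
    day5 = None if pd.isna(day5) else int(day5)
    kwargs = {
        "patient_id": str(row["patient_id"]),
        "age": int(row["age"]),
        "sex": str(row["sex"]),
        "nihss_admission": int(row["nihss_admission"]),
        "nihss_day5": day5,
        "territories": terrs,
        "mca_fraction": float(row["mca_fraction"]),
    }
    for f in BOOL_FIELDS:
        v = row[f]
        if pd.isna(v):
            raise RecordValidationError([(f, "missing indicator value")])
        kwargs[f] = int(v)
    return PatientRecord(**kwargs)


def frame_to_records(
    frame: pd.DataFrame, collect_errors: bool = False
) -> list[PatientRecord] | tuple[list[PatientRecord], list[RowError]]:
    """Validate a cohort DataFrame into records.

    With ``collect_errors`` the return value is ``(records, errors)`` and
    invalid rows are skipped; otherwise the first bad row raises.
    """
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    records: list[PatientRecord] = []
    errors: list[RowError] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            records.append(_row_to_record(row))
        except (RecordValidationError, ValueError, TypeError) as exc:
            if not collect_errors:
                raise
            detail = exc.errors if isinstance(exc, RecordValidationError) else [
                ("row", str(exc))
            ]
            errors.append(RowError(i, detail))
    if collect_errors:
        return records, errors
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        d = asdict(rec)
        d["territories"] = ";".join(
            sorted(d["territories"], key=["deep", "superior", "posterior"].index)
        )
        for f in BOOL_FIELDS:
            d[f] = int(d[f])
        rows.append(d)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def read_cohort(
    path: str | Path, collect_errors: bool = True
) -> tuple[list[PatientRecord], list[RowError]]:
    """Read and validate a cohort CSV.

    Returns ``(records, errors)``: invalid rows are reported with their row
    number and offending field rather than aborting the load.  Pass
    ``collect_errors=False`` to raise on the first invalid row instead
    (the error list is then always empty).
    """
    frame = pd.read_csv(path, dtype={"patient_id": str, "territories": str},
                        float_precision="round_trip")
    if collect_errors:
        return frame_to_records(frame, collect_errors=True)
    return frame_to_records(frame), []


def write_cohort(records: list[PatientRecord], path: str | Path) -> None:
    """Write records as a cohort CSV (the schema `read_cohort` expects)."""
    frame = records_to_frame(records)
    frame["nihss_day5"] = frame["nihss_day5"].astype("Int64")
    frame.to_csv(path, index=False)
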