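"""CSV reading/writing for patient tables.

Expected header::

    patient_id,age,bmi,dm_duration,microvascular,macrovascular,
    insulin_use,c_peptide_stim[,hba1c,procedure,on_medication,remission]

Booleans are accepted as 0/1, true/false, yes/no (case-insensitive).
Malformed rows raise :class:`~drscore.core.ValidationError` naming the
row number and field — never silently skipped or imputed.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import pandas as pd

from .core import COMPONENTS, PatientRecord, Procedure, ValidationError, score_patient

__all__ = ["read_patients", "patients_to_frame", "score_frame"]

_REQUIRED = (
    "patient_id",
    "age",
    "bmi",
    "dm_duration",
    "microvascular",
    "macrovascular",
    "insulin_use",
    "c_peptide_stim",
)
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("1.0", "0.0"):  # pandas may have read the column as float
        text = text[0]
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(
        f"row {row}: column {column!r}: cannot parse boolean from {value!r} "
        "(accepted: 0/1, true/false, yes/no)"
    )


def _parse_float(value, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: column {column!r}: cannot parse number from {value!r}"
        ) from None


def read_patients(path: "str | Path") -> List[PatientRecord]:
    """Read a patient CSV into validated records.

    Row numbers in error messages count data rows from 1 (the header
    is row 0).
    """
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: input file is empty") from None
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise ValidationError(f"{path}: no patient rows")

    records: List[PatientRecord] = []
    for i, raw in enumerate(frame.to_dict("records"), start=1):
        def has(col: str) -> bool:
            return col in raw and raw[col] is not None and str(raw[col]).strip() != "" and str(raw[col]).lower() != "nan"

        for col in _REQUIRED:
            if not has(col):
                raise ValidationError(f"row {i}: column {col!r} is missing or empty")
        procedure: Optional[Procedure] = None
        if has("procedure"):
            procedure = Procedure.coerce(raw["procedure"])
        records.append(
            PatientRecord(
                patient_id=str(raw["patient_id"]).strip(),
                age=_parse_float(raw["age"], i, "age"),
                bmi=_parse_float(raw["bmi"], i, "bmi"),
                dm_duration=_parse_float(raw["dm_duration"], i, "dm_duration"),
                microvascular=_parse_bool(raw["microvascular"], i, "microvascular"),
                macrovascular=_parse_bool(raw["macrovascular"], i, "macrovascular"),
                insulin_use=_parse_bool(raw["insulin_use"], i, "insulin_use"),
                c_peptide_stim=_parse_float(raw["c_peptide_stim"], i, "c_peptide_stim"),
                hba1c=_parse_float(raw["hba1c"], i, "hba1c") if has("hba1c") else None,
                procedure=procedure,
                on_diabetes_medication=(
                    _parse_bool(raw["on_medication"], i, "on_medication")
                    if has("on_medication")
                    else None
                ),
                observed_remission=(
                    _parse_bool(raw["remission"], i, "remission") if has("remission") else None
                ),
            )
        )
    return records


def patients_to_frame(records: List[PatientRecord]) -> pd.DataFrame:
    """Records → DataFrame with the canonical CSV columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "bmi": r.bmi,
                "dm_duration": r.dm_duration,
                "microvascular": int(r.microvascular),
                "macrovascular": int(r.macrovascular),
                "insulin_use": int(r.insulin_use),
                "c_peptide_stim": r.c_peptide_stim,
                "hba1c": r.hba1c,
                "procedure": r.procedure.value if r.procedure else None,
                "on_medication": None
                if r.on_diabetes_medication is None
                else int(r.on_diabetes_medication),
                "remission": None
                if r.observed_remission is None
                else int(r.observed_remission),
            }
        )
    return pd.DataFrame(rows)


def score_frame(records: List[PatientRecord]) -> pd.DataFrame:
    """Score records and append drs_* columns to the canonical frame."""
    frame = patients_to_frame(records)
    results = [score_patient(r) for r in records]
    for name in COMPONENTS:
        frame[f"drs_{name}"] = [res.subscores[name] for res in results]
    frame["drs_total"] = [res.total for res in results]
    frame["drs_grade"] = [res.grade.value for res in results]
    return frame
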