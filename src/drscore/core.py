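"""Patient data model and the seven-component Diabetes Remission Score.

The Diabetes Remission Score (DRS) dichotomizes seven preoperative
variables — age, BMI, diabetes duration, microvascular and macrovascular
complications, preoperative insulin use, and stimulated C-peptide — into
1 (favourable) or 2 (unfavourable) points each, for a total of 7-14.
Lower totals indicate a higher probability of post-surgical diabetes
remission.  Totals are graded as mild (7-8), moderate (9-11) or severe
(12-14) diabetes.

The cut-offs are fixed clinical thresholds, not tunable parameters:

========================  =============  =============
component                 score 1        score 2
========================  =============  =============
age (years)               30-60 incl.    <30 or >60
BMI (kg/m^2)              >= 27          < 27
diabetes duration (yr)    < 10           >= 10
microvascular compl.      no             yes
macrovascular compl.      no             yes
preoperative insulin      no             yes
stimulated C-peptide      >= 4 ng/mL     < 4 ng/mL
========================  =============  =============

Missing or non-finite scoring inputs raise :class:`ValidationError`;
a one-point error in a 7-14 score is material, so nothing is imputed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "Procedure",
    "Grade",
    "PatientRecord",
    "DRSResult",
    "ValidationError",
    "COMPONENTS",
    "score_patient",
    "grade_for_total",
    "SCORE_MIN",
    "SCORE_MAX",
]

SCORE_MIN = 7
SCORE_MAX = 14

#: The seven scored components, in reporting order.
COMPONENTS = (
    "age",
    "bmi",
    "dm_duration",
    "microvascular",
    "macrovascular",
    "insulin_use",
    "c_peptide_stim",
)


class ValidationError(ValueError):
    """A patient record field is missing, malformed or non-finite."""


class Procedure(str, enum.Enum):
    """Surgical procedure: ileal interposition with (diverted) sleeve gastrectomy."""

    IISG = "IISG"
    IIDSG = "IIDSG"

    @classmethod
    def coerce(cls, value: "Procedure | str") -> "Procedure":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise ValidationError(
                f"unknown procedure {value!r}; expected IISG or IIDSG"
            ) from None


class Grade(str, enum.Enum):
    """Severity grade derived from the DRS total."""

    grade1 = "grade1"  # mild, DRS 7-8
    grade2 = "grade2"  # moderate, DRS 9-11
    grade3 = "grade3"  # severe, DRS 12-14


@dataclass(frozen=True)
class PatientRecord:
    """One patient's scoring inputs plus optional clinical fields.

    The seven scoring fields (age, bmi, dm_duration, microvascular,
    macrovascular, insulin_use, c_peptide_stim) are mandatory for
    scoring.  ``microvascular``/``macrovascular`` are pre-adjudicated
    flags; conventionally retinopathy/nephropathy/neuropathy and
    coronary/cerebrovascular/peripheral arterial disease respectively,
    but the package does not re-adjudicate diagnoses.
    """

    patient_id: str
    age: float
    bmi: float
    dm_duration: float
    microvascular: bool
    macrovascular: bool
    insulin_use: bool
    c_peptide_stim: float
    hba1c: Optional[float] = None
    procedure: Optional[Procedure] = None
    on_diabetes_medication: Optional[bool] = None
    observed_remission: Optional[bool] = None
    #: optional pre-adjudicated exclusion flags, e.g. {"pregnancy": True}
    exclusions: Mapping[str, bool] = field(default_factory=dict)
    stable_weight: Optional[bool] = None


def _require_finite(record: PatientRecord, name: str, *, positive: bool = False) -> float:
    value = getattr(record, name)
    if value is None:
        raise ValidationError(f"patient {record.patient_id!r}: field {name!r} is missing")
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"patient {record.patient_id!r}: field {name!r} is not numeric: {value!r}"
        ) from None
    if not math.isfinite(value):
        raise ValidationError(f"patient {record.patient_id!r}: field {name!r} is not finite")
    if value < 0 or (positive and value == 0):
        raise ValidationError(
            f"patient {record.patient_id!r}: field {name!r} must be "
            f"{'positive' if positive else 'non-negative'}, got {value}"
        )
    return value


def _require_bool(record: PatientRecord, name: str) -> bool:
    value = getattr(record, name)
    if value is None:
        raise ValidationError(f"patient {record.patient_id!r}: field {name!r} is missing")
    if not isinstance(value, (bool,)):
        raise ValidationError(
            f"patient {record.patient_id!r}: field {name!r} must be boolean, got {value!r}"
        )
    return value


def grade_for_total(total: int) -> Grade:
    """Map a DRS total to its severity grade (7-8 / 9-11 / 12-14)."""
    if not (SCORE_MIN <= total <= SCORE_MAX):
        raise ValidationError(f"DRS total must be in [{SCORE_MIN}, {SCORE_MAX}], got {total}")
    if total <= 8:
        return Grade.grade1
    if total <= 11:
        return Grade.grade2
    return Grade.grade3


@dataclass(frozen=True)
class DRSResult:
    """Per-component subscores (each 1 or 2), their total (7-14) and grade."""

    subscores: Mapping[str, int]
    total: int
    grade: Grade

    def __post_init__(self) -> None:
        if set(self.subscores) != set(COMPONENTS):
            raise ValidationError("subscores must cover exactly the seven DRS components")
        if any(s not in (1, 2) for s in self.subscores.values()):
            raise ValidationError("every subscore must be 1 or 2")
        if self.total != sum(self.subscores.values()):
            raise ValidationError("total must equal the sum of the subscores")


def score_patient(patient: PatientRecord) -> DRSResult:
    """Compute the DRS for one patient.

    Pure and deterministic.  Thresholds are applied to the raw real
    values (no rounding): age 30 and 60, BMI 27 and C-peptide 4 are
    favourable boundaries (inclusive), duration 10 is unfavourable
    (``>= 10`` scores 2).

    Raises
    ------
    ValidationError
        If any of the seven scoring fields is missing or non-finite.
    """
    age = _require_finite(patient, "age")
    bmi = _require_finite(patient, "bmi", positive=True)
    duration = _require_finite(patient, "dm_duration")
    c_peptide = _require_finite(patient, "c_peptide_stim")
    micro = _require_bool(patient, "microvascular")
    macro = _require_bool(patient, "macrovascular")
    insulin = _require_bool(patient, "insulin_use")

    subscores = {
        "age": 1 if 30 <= age <= 60 else 2,
        "bmi": 1 if bmi >= 27 else 2,
        "dm_duration": 1 if duration < 10 else 2,
        "microvascular": 2 if micro else 1,
        "macrovascular": 2 if macro else 1,
        "insulin_use": 2 if insulin else 1,
        "c_peptide_stim": 1 if c_peptide >= 4 else 2,
    }
    total = sum(subscores.values())
    return DRSResult(subscores=subscores, total=total, grade=grade_for_total(total))
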