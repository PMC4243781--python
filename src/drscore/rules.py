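"""Study eligibility criteria and the diabetes-remission definition.

Inclusion criteria (checked per procedure):

* age 25-70 years (inclusive at both ends),
* type 2 diabetes duration > 1 year (> 5 years for IIDSG),
* poor glycaemic control, HbA1c > 7 %,
* BMI >= 20 kg/m^2 (> 18.5 kg/m^2 for IIDSG),
* stimulated C-peptide > 1.5 ng/mL (strict),
* stable weight (accepted as an optional pre-adjudicated flag; there is
  no operational definition, so it is never computed from data).

Exclusions (type 1 diabetes, undetectable fasting C-peptide,
ketoacidosis within 6 months, pregnancy, severe hepatic / pulmonary /
psychiatric disease) enter as optional boolean flags on the record.

Remission is defined as HbA1c < 6.5 % without any glucose-lowering
medication — comparable to ADA partial remission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

from .core import PatientRecord, Procedure, ValidationError

__all__ = [
    "EligibilityVerdict",
    "check_eligibility",
    "classify_remission",
    "EXCLUSION_FLAGS",
    "REMISSION_HBA1C_THRESHOLD",
]

REMISSION_HBA1C_THRESHOLD = 6.5

#: Recognised exclusion-flag identifiers (value True ⇒ excluded).
EXCLUSION_FLAGS = (
    "type_1_diabetes",
    "undetectable_fasting_c_peptide",
    "recent_ketoacidosis",
    "pregnancy",
    "severe_comorbidity",
)


@dataclass(frozen=True)
class EligibilityVerdict:
    """Outcome of the eligibility screen: every violated criterion is listed."""

    eligible: bool
    failed_criteria: List[str]

    def __post_init__(self) -> None:
        if self.eligible != (len(self.failed_criteria) == 0):
            raise ValidationError("eligible must be equivalent to an empty failure list")


def check_eligibility(patient: PatientRecord, procedure: "Procedure | str") -> EligibilityVerdict:
    """Screen one patient against the study's per-procedure inclusion criteria.

    HbA1c is required for this check (glycaemic-control criterion);
    a missing value is a validation error, not a silent pass.
    """
    procedure = Procedure.coerce(procedure)
    if patient.hba1c is None or not math.isfinite(float(patient.hba1c)):
        raise ValidationError(
            f"patient {patient.patient_id!r}: hba1c is required for eligibility screening"
        )

    failed: List[str] = []
    if not (25 <= patient.age <= 70):
        failed.append("age_window_25_70")
    min_duration = 5.0 if procedure is Procedure.IIDSG else 1.0
    if not (patient.dm_duration > min_duration):
        failed.append("dm_duration_gt_%d" % int(min_duration))
    if not (float(patient.hba1c) > 7.0):
        failed.append("hba1c_above_7")
    if procedure is Procedure.IIDSG:
        if not (patient.bmi > 18.5):
            failed.append("bmi_above_18.5")
    else:
        if not (patient.bmi >= 20.0):
            failed.append("bmi_at_least_20")
    if not (patient.c_peptide_stim > 1.5):
        failed.append("c_peptide_above_1.5")
    if patient.stable_weight is False:
        failed.append("stable_weight")
    for flag in EXCLUSION_FLAGS:
        if patient.exclusions.get(flag, False):
            failed.append("excluded_" + flag)

    return EligibilityVerdict(eligible=not failed, failed_criteria=failed)


def classify_remission(hba1c: float, on_diabetes_medication: bool) -> bool:
    """True iff HbA1c < 6.5 % and no glucose-lowering medication is required.

    The inequality is strict: HbA1c exactly 6.5 % is not remission.
    """
    hba1c = float(hba1c)
    if not math.isfinite(hba1c) or hba1c <= 0:
        raise ValidationError(f"hba1c must be finite and positive, got {hba1c!r}")
    if not isinstance(on_diabetes_medication, bool):
        raise ValidationError("on_diabetes_medication must be boolean")
    return hba1c < REMISSION_HBA1C_THRESHOLD and not on_diabetes_medication
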