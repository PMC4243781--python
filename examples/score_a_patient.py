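"""Score a single patient and read off the grade.

Each of the seven preoperative variables contributes 1 (favourable) or
2 (unfavourable) points, so the total runs 7-14; grade 1 (7-8) is mild,
grade 2 (9-11) moderate, grade 3 (12-14) severe diabetes.
"""

from drscore import PatientRecord, score_patient

patient = PatientRecord(
    patient_id="example-01",
    age=58,                 # within 30-60 -> 1 point
    bmi=24.5,               # below 27 -> 2 points
    dm_duration=12,         # >= 10 years -> 2 points
    microvascular=True,     # retinopathy -> 2 points
    macrovascular=False,    # 1 point
    insulin_use=True,       # 2 points
    c_peptide_stim=4.8,     # >= 4 ng/mL -> 1 point
)

result = score_patient(patient)
print("subscores:", dict(result.subscores))
print("total DRS:", result.total)
print("grade:    ", result.grade.value)
# An 11 sits at the top of the moderate band: remission is still
# plausible after the diverted procedure, but not after IISG.
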