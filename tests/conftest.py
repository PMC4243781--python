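import pytest

from drscore import PatientRecord


def make_record(**overrides) -> PatientRecord:
    """A fully favourable, eligible IISG patient unless overridden."""
    base = dict(
        patient_id="t-001",
        age=45.0,
        bmi=30.0,
        dm_duration=6.0,
        microvascular=False,
        macrovascular=False,
        insulin_use=False,
        c_peptide_stim=5.0,
        hba1c=8.0,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def favourable_record() -> PatientRecord:
    return make_record()
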