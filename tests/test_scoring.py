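"""The seven-component score: cut-offs, bounds, monotonicity, validation."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drscore import COMPONENTS, Grade, ValidationError, grade_for_total, score_patient
from drscore.core import SCORE_MAX, SCORE_MIN

from .conftest import make_record


class TestExamples:
    def test_all_favourable_scores_seven(self, favourable_record):
        result = score_patient(favourable_record)
        assert set(result.subscores.values()) == {1}
        assert result.total == 7
        assert result.grade is Grade.grade1

    def test_all_unfavourable_scores_fourteen(self):
        record = make_record(
            age=72, bmi=22, dm_duration=12, microvascular=True,
            macrovascular=True, insulin_use=True, c_peptide_stim=2.0,
        )
        result = score_patient(record)
        assert set(result.subscores.values()) == {2}
        assert result.total == 14
        assert result.grade is Grade.grade3

    def test_boundary_combination_scores_nine(self):
        # every numeric input sits exactly on its cut-off
        record = make_record(
            age=60, bmi=27, dm_duration=10, insulin_use=True, c_peptide_stim=4.0
        )
        result = score_patient(record)
        assert result.subscores == {
            "age": 1, "bmi": 1, "dm_duration": 2, "microvascular": 1,
            "macrovascular": 1, "insulin_use": 2, "c_peptide_stim": 1,
        }
        assert result.total == 9
        assert result.grade is Grade.grade2


#: (field, value, expected subscore) — each numeric cut-off at, just
#: below and just above the threshold.
BOUNDARY_CASES = [
    ("age", 29.9, 2), ("age", 30.0, 1), ("age", 30.1, 1),
    ("age", 59.9, 1), ("age", 60.0, 1), ("age", 60.1, 2),
    ("bmi", 26.9, 2), ("bmi", 27.0, 1), ("bmi", 27.1, 1),
    ("dm_duration", 9.9, 1), ("dm_duration", 10.0, 2), ("dm_duration", 10.1, 2),
    ("c_peptide_stim", 3.9, 2), ("c_peptide_stim", 4.0, 1), ("c_peptide_stim", 4.1, 1),
]


@pytest.mark.parametrize("field,value,expected", BOUNDARY_CASES)
def test_numeric_cutoff_boundaries(field, value, expected):
    result = score_patient(make_record(**{field: value}))
    assert result.subscores[field] == expected


def test_exhaustive_enumeration_spans_7_to_14():
    """All 2^7 favourable/unfavourable combinations hit exactly 7..14."""
    favourable = dict(
        age=45, bmi=30, dm_duration=5, microvascular=False,
        macrovascular=False, insulin_use=False, c_peptide_stim=5.0,
    )
    unfavourable = dict(
        age=75, bmi=22, dm_duration=15, microvascular=True,
        macrovascular=True, insulin_use=True, c_peptide_stim=2.0,
    )
    totals = set()
    for mask in itertools.product([0, 1], repeat=7):
        fields = {
            name: (unfavourable if bit else favourable)[name]
            for name, bit in zip(COMPONENTS, mask)
        }
        result = score_patient(make_record(**fields))
        assert result.total == 7 + sum(mask)
        totals.add(result.total)
    assert totals == set(range(SCORE_MIN, SCORE_MAX + 1))


@given(
    age=st.floats(0, 110, allow_nan=False),
    bmi=st.floats(10, 80, allow_nan=False),
    duration=st.floats(0, 60, allow_nan=False),
    micro=st.booleans(),
    macro=st.booleans(),
    insulin=st.booleans(),
    c_pep=st.floats(0, 20, allow_nan=False),
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_total_is_component_sum_within_bounds(age, bmi, duration, micro, macro, insulin, c_pep):
    result = score_patient(
        make_record(
            age=age, bmi=bmi, dm_duration=duration, microvascular=micro,
            macrovascular=macro, insulin_use=insulin, c_peptide_stim=c_pep,
        )
    )
    assert SCORE_MIN <= result.total <= SCORE_MAX
    assert result.total == sum(result.subscores.values())
    assert result.grade is grade_for_total(result.total)


@pytest.mark.parametrize("component", COMPONENTS)
def test_single_component_flip_adds_exactly_one_point(component, favourable_record):
    unfavourable_value = {
        "age": 75, "bmi": 22, "dm_duration": 15, "microvascular": True,
        "macrovascular": True, "insulin_use": True, "c_peptide_stim": 2.0,
    }[component]
    base = score_patient(favourable_record)
    flipped = score_patient(make_record(**{component: unfavourable_value}))
    assert flipped.total == base.total + 1
    for name in COMPONENTS:
        if name != component:
            assert flipped.subscores[name] == base.subscores[name]
    assert flipped.subscores[component] == 2


class TestValidation:
    @pytest.mark.parametrize("field", ["age", "bmi", "dm_duration", "c_peptide_stim"])
    def test_missing_numeric_field_raises_naming_it(self, field):
        with pytest.raises(ValidationError, match=field):
            score_patient(make_record(**{field: None}))

    @pytest.mark.parametrize("field", ["microvascular", "macrovascular", "insulin_use"])
    def test_missing_flag_raises_naming_it(self, field):
        with pytest.raises(ValidationError, match=field):
            score_patient(make_record(**{field: None}))

    def test_non_finite_value_raises(self):
        with pytest.raises(ValidationError, match="age"):
            score_patient(make_record(age=math.nan))
        with pytest.raises(ValidationError, match="c_peptide_stim"):
            score_patient(make_record(c_peptide_stim=math.inf))

    def test_grade_for_out_of_range_total_raises(self):
        with pytest.raises(ValidationError):
            grade_for_total(6)
        with pytest.raises(ValidationError):
            grade_for_total(15)
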