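"""Eligibility screening and the remission definition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drscore import ValidationError, check_eligibility, classify_remission
from drscore.simulate import default_config, generate_cohort

from .conftest import make_record


class TestEligibility:
    def test_fully_qualifying_record_is_eligible(self, favourable_record):
        for proc in ("IISG", "IIDSG"):
            verdict = check_eligibility(favourable_record, proc)
            assert verdict.eligible
            assert verdict.failed_criteria == []

    def test_age_below_window(self):
        verdict = check_eligibility(make_record(age=24), "IISG")
        assert not verdict.eligible
        assert verdict.failed_criteria == ["age_window_25_70"]

    @pytest.mark.parametrize("age,ok", [(25, True), (70, True), (24.9, False), (70.1, False)])
    def test_age_window_inclusive_at_both_ends(self, age, ok):
        assert check_eligibility(make_record(age=age), "IISG").eligible is ok

    def test_hba1c_must_exceed_seven(self):
        verdict = check_eligibility(make_record(hba1c=6.8), "IISG")
        assert verdict.failed_criteria == ["hba1c_above_7"]
        assert check_eligibility(make_record(hba1c=7.0), "IISG").eligible is False
        assert check_eligibility(make_record(hba1c=7.1), "IISG").eligible is True

    def test_bmi_bound_differs_by_procedure(self):
        record = make_record(bmi=19.0)
        assert not check_eligibility(record, "IISG").eligible  # needs >= 20
        assert check_eligibility(record, "IIDSG").eligible     # needs > 18.5
        assert check_eligibility(make_record(bmi=20.0), "IISG").eligible
        assert not check_eligibility(make_record(bmi=18.5), "IIDSG").eligible

    def test_c_peptide_bound_is_strict(self):
        verdict = check_eligibility(make_record(c_peptide_stim=1.5), "IISG")
        assert verdict.failed_criteria == ["c_peptide_above_1.5"]

    @pytest.mark.parametrize(
        "duration,proc,ok",
        [(1.0, "IISG", False), (1.1, "IISG", True), (5.0, "IIDSG", False), (5.1, "IIDSG", True)],
    )
    def test_duration_bounds_strict_and_per_procedure(self, duration, proc, ok):
        assert check_eligibility(make_record(dm_duration=duration), proc).eligible is ok

    def test_exclusion_flags_each_add_a_criterion(self):
        record = make_record(exclusions={"pregnancy": True, "recent_ketoacidosis": True})
        verdict = check_eligibility(record, "IISG")
        assert not verdict.eligible
        assert set(verdict.failed_criteria) == {
            "excluded_pregnancy",
            "excluded_recent_ketoacidosis",
        }

    def test_unstable_weight_flag_fails(self):
        verdict = check_eligibility(make_record(stable_weight=False), "IISG")
        assert verdict.failed_criteria == ["stable_weight"]
        assert check_eligibility(make_record(stable_weight=True), "IISG").eligible

    def test_missing_hba1c_is_an_error(self):
        with pytest.raises(ValidationError, match="hba1c"):
            check_eligibility(make_record(hba1c=None), "IISG")

    def test_unknown_procedure_is_an_error(self):
        with pytest.raises(ValidationError, match="procedure"):
            check_eligibility(make_record(), "RYGB")

    def test_every_violated_criterion_is_listed(self):
        record = make_record(age=80, hba1c=6.0, c_peptide_stim=1.0)
        verdict = check_eligibility(record, "IISG")
        assert set(verdict.failed_criteria) == {
            "age_window_25_70",
            "hba1c_above_7",
            "c_peptide_above_1.5",
        }


def test_filter_count_matches_independent_criterion_intersection():
    """Eligible count equals intersecting each criterion applied separately."""
    cohort = generate_cohort(default_config("IISG", n=30, seed=7))
    # perturb some records so that both verdicts occur
    from dataclasses import replace

    perturbed = []
    for i, rec in enumerate(cohort):
        if i % 5 == 0:
            rec = replace(rec, age=22.0)
        if i % 7 == 0:
            rec = replace(rec, hba1c=6.5)
        perturbed.append(rec)

    criteria = [
        lambda r: 25 <= r.age <= 70,
        lambda r: r.dm_duration > 1,
        lambda r: r.hba1c > 7,
        lambda r: r.bmi >= 20,
        lambda r: r.c_peptide_stim > 1.5,
    ]
    oracle = sum(all(c(r) for c in criteria) for r in perturbed)
    package = sum(check_eligibility(r, "IISG").eligible for r in perturbed)
    assert package == oracle
    assert 0 < package < len(perturbed)


class TestRemission:
    @pytest.mark.parametrize(
        "hba1c,on_meds,expected",
        [(6.4, False, True), (6.4, True, False), (6.5, False, False), (6.6, False, False)],
    )
    def test_definition(self, hba1c, on_meds, expected):
        assert classify_remission(hba1c, on_meds) is expected

    @given(
        h1=st.floats(4.0, 14.0, allow_nan=False),
        h2=st.floats(4.0, 14.0, allow_nan=False),
        on_meds=st.booleans(),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_anti_monotone_in_hba1c(self, h1, h2, on_meds):
        lo, hi = sorted((h1, h2))
        assert classify_remission(hi, on_meds) <= classify_remission(lo, on_meds)

    def test_invalid_hba1c_raises(self):
        with pytest.raises(ValidationError):
            classify_remission(0.0, False)
        with pytest.raises(ValidationError):
            classify_remission(float("nan"), False)
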