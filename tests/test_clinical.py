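"""Clinical derivations: diabetes rule, BP averaging, risk strata, matching,
Hardy-Weinberg equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskmvpa.clinical import (MissingDataError, balanced_split_pairs,
                               diabetes_status, hardy_weinberg_test,
                               match_apoe_noncarriers, match_groups,
                               mean_blood_pressure, risk_group, risk_groups)
from conftest import make_cohort_table


@pytest.mark.parametrize("glucose,meds,expected", [
    (126.0, False, True),    # threshold itself is diabetic
    (125.0, False, False),
    (90.0, True, True),      # treatment alone suffices
    (300.0, True, True),
])
def test_diabetes_rule(glucose, meds, expected):
    assert diabetes_status(glucose, meds) is expected


def test_diabetes_missing_glucose():
    assert diabetes_status(float("nan"), True) is True
    with pytest.raises(MissingDataError):
        diabetes_status(float("nan"), False)


@pytest.mark.parametrize("readings,expected", [
    ((140, 130, 126), 128.0),
    ((999, 120, 120), 120.0),   # first reading has no influence
    ((118, 121, 124), 122.5),
])
def test_mean_blood_pressure(readings, expected):
    assert mean_blood_pressure(readings) == expected


def test_mean_blood_pressure_requires_three_readings():
    with pytest.raises(MissingDataError):
        mean_blood_pressure((120, 118))


@given(first=st.floats(50, 300), second=st.floats(50, 300), third=st.floats(50, 300))
@settings(max_examples=50, derandomize=True)
def test_first_reading_invariance(first, second, third):
    assert mean_blood_pressure((first, second, third)) == \
        mean_blood_pressure((999.0, second, third))


@pytest.mark.parametrize("score,gender,expected", [
    (5, "male", "low"), (6, "male", "medium"), (8, "male", "medium"),
    (9, "male", "high"), (0, "male", "low"),
    (9, "female", "low"), (10, "female", "medium"), (14, "female", "medium"),
    (15, "female", "high"),
])
def test_risk_group_cutoffs(score, gender, expected):
    assert risk_group(score, gender) == expected


def test_risk_group_total_and_exhaustive():
    for gender in ("male", "female"):
        for score in range(0, 40):
            assert risk_group(score, gender) in {"low", "medium", "high"}
    with pytest.raises(ValueError):
        risk_group(5, "unknown")
    with pytest.raises(ValueError):
        risk_group(-1, "male")


def test_match_groups_perfect_matching():
    # identical (gender, age) multisets in both groups -> everyone matched
    cohort = make_cohort_table(
        genders=["male", "male", "female", "female"] * 2,
        ages=[68, 70, 69, 72] * 2,
        fchdr=[2, 3, 5, 6, 10, 12, 16, 18],  # first 4 low, last 4 high
    )
    res = match_groups(cohort, "high", "low", age_caliper=2)
    assert res.n_pairs == 4
    assert res.discarded == []


def test_match_groups_gender_constraint():
    cohort = make_cohort_table(
        genders=["male"] * 3 + ["female"] * 3,
        ages=[70] * 6,
        fchdr=[2, 3, 4, 16, 17, 18],  # all males low, all females high
    )
    res = match_groups(cohort, "high", "low", age_caliper=100)
    assert res.n_pairs == 0
    assert len(res.discarded) == 6


def test_match_groups_counting_with_infinite_caliper():
    # group sizes (9M, 33F) vs (44M, 17F): within-gender minima give
    # 9 male + 17 female = 26 pairs
    genders = ["male"] * 9 + ["female"] * 33 + ["male"] * 44 + ["female"] * 17
    ages = [66 + i % 10 for i in range(len(genders))]
    fchdr = [2] * 9 + [5] * 33 + [10] * 44 + [16] * 17  # males low/high, females low/high
    cohort = make_cohort_table(genders=genders, ages=ages, fchdr=fchdr)
    res = match_groups(cohort, "high", "low", age_caliper=np.inf)
    assert res.n_pairs == 26


def test_match_groups_symmetric_in_group_order(default_cohort):
    cohort = default_cohort[0]
    ab = match_groups(cohort, "high", "low", age_caliper=2)
    ba = match_groups(cohort, "low", "high", age_caliper=2)
    assert {frozenset(p) for p in ab.pairs} == {frozenset(p) for p in ba.pairs}


def test_match_apoe_empty_carriers(default_cohort):
    res = match_apoe_noncarriers(default_cohort[0], carriers=set())
    assert res.pairs == []


def test_match_apoe_exact_balance():
    # non-carrier pool mirrors the carriers in (gender, age, fchdr)
    cohort = make_cohort_table(
        genders=["female", "male"] * 4,
        ages=[68, 70, 72, 74] * 2,
        fchdr=[4, 8, 12, 6] * 2,
        apoe4=[1, 1, 1, 1, 0, 0, 0, 0],
    )
    res = match_apoe_noncarriers(cohort)
    assert len(res.pairs) == 4 and not res.warnings
    by_id = cohort.set_index("subject_id")
    for carrier, control in res.pairs:
        assert by_id.loc[carrier, "gender"] == by_id.loc[control, "gender"]
        assert by_id.loc[carrier, "age"] == by_id.loc[control, "age"]
        assert by_id.loc[carrier, "fchdr"] == by_id.loc[control, "fchdr"]


def test_match_apoe_covers_all_carriers():
    # 36 carriers with a compatible pool of >= 36 -> full match
    rng = np.random.default_rng(1)
    n = 120
    cohort = make_cohort_table(
        genders=list(rng.choice(["male", "female"], n)),
        ages=list(rng.integers(66, 76, n)),
        fchdr=list(rng.integers(0, 20, n)),
        apoe4=[1] * 36 + [0] * (n - 36),
    )
    res = match_apoe_noncarriers(cohort)
    assert len(res.pairs) == 36
    controls = [b for _, b in res.pairs]
    assert len(set(controls)) == 36  # each non-carrier used once


def test_hardy_weinberg_brute_force_oracle():
    # independent arithmetic: p = (2*5 + 26) / 144, expected (p^2, 2pq, q^2)*72
    counts = (5, 26, 41)
    n = sum(counts)
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1 - p
    expected = [p * p * n, 2 * p * q * n, q * q * n]
    chi_hand = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    chi2, pval = hardy_weinberg_test(*counts)
    assert chi2 == pytest.approx(chi_hand, rel=1e-12)
    assert 0.0 <= pval <= 1.0


@pytest.mark.parametrize("counts", [(25, 10, 1), (49, 42, 9), (0, 0, 100)])
def test_hardy_weinberg_exact_fit_and_monomorphic(counts):
    chi2, pval = hardy_weinberg_test(*counts)
    assert chi2 == pytest.approx(0.0, abs=1e-9)


def test_hardy_weinberg_all_zero_counts_rejected():
    with pytest.raises(ValueError):
        hardy_weinberg_test(0, 0, 0)


def test_balanced_split_pairs_structure(default_cohort):
    cohort = default_cohort[0]
    pairs, labels = balanced_split_pairs(cohort)
    flat = [s for p in pairs for s in p]
    assert len(flat) == len(set(flat))
    assert (labels == 1).sum() == (labels == -1).sum() == len(pairs)
    by_id = cohort.set_index("subject_id")
    for a, b in pairs:
        assert by_id.loc[a, "gender"] == by_id.loc[b, "gender"]
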