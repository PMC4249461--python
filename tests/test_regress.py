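"""Support-vector regression: target normalization, leave-one-out CV,
metric closed forms, and the single-factor battery."""

import numpy as np
import pytest

from riskmvpa.regress import (DegenerateTargetError, FACTORS,
                              classify_dichotomous_factor, factor_values,
                              loo_svr, regression_metrics, run_factor_battery,
                              subgroup_indices, znormalize)
from riskmvpa.kernels import linear_kernel
from conftest import make_cohort_table


def test_znormalize_simple():
    z, mean, sd = znormalize([1.0, 2.0, 3.0])
    np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
    assert (mean, sd) == (2.0, 1.0)


def test_znormalize_idempotent(rng):
    z, _, _ = znormalize(rng.normal(size=50))
    z2, mean, sd = znormalize(z)
    np.testing.assert_allclose(z2, z, atol=1e-12)
    assert mean == pytest.approx(0.0, abs=1e-12)
    assert sd == pytest.approx(1.0, abs=1e-12)


def test_znormalize_constant_target_rejected():
    with pytest.raises(DegenerateTargetError):
        znormalize([5.0, 5.0, 5.0])


def test_regression_metrics_closed_forms(rng):
    z, _, _ = znormalize(rng.normal(size=40))
    n = z.size
    r, mse = regression_metrics(z, z)
    assert (r, mse) == (pytest.approx(1.0), pytest.approx(0.0))
    r, mse = regression_metrics(z, -z)
    assert r == pytest.approx(-1.0)
    assert mse == pytest.approx(4 * (n - 1) / n)  # mean of (2z)^2 at sample SD 1
    r, mse = regression_metrics(z, np.zeros(n))
    assert np.isnan(r)  # constant prediction: r undefined, MSE still returned
    assert mse == pytest.approx((n - 1) / n)  # the near-1 scale of a mean predictor


def test_loo_svr_recovers_strong_signal(strong_kernel, strong_cohort):
    K, _ = strong_kernel
    cohort = strong_cohort[0]
    res = loo_svr(K, cohort["fchdr"].to_numpy(dtype=float))
    assert res.r >= 0.7
    assert res.mse < 1.0  # materially below the mean-predictor scale


def test_loo_svr_null_images_near_zero(null_kernel60, null_cohort60):
    K, _ = null_kernel60
    cohort = null_cohort60[0]
    res = loo_svr(K, cohort["fchdr"].to_numpy(dtype=float))
    assert abs(res.r) < 3 / np.sqrt(len(cohort))
    # no signal: error never drops materially below the mean-predictor scale
    assert res.mse > 0.8


def test_loo_svr_minimum_size_and_degenerate_target():
    with pytest.raises(ValueError, match="at least 10"):
        loo_svr(np.eye(4), [1.0, 2.0, 3.0, 4.0])
    with pytest.raises(DegenerateTargetError):
        loo_svr(np.eye(12), np.ones(12))


def test_factor_values_blood_pressure_discards_first_reading():
    cohort = make_cohort_table(genders=["male"] * 3, ages=[70] * 3,
                               fchdr=[1, 2, 3],
                               bp1_sys=[999.0, 999.0, 999.0],
                               bp2_sys=[120.0, 130.0, 140.0],
                               bp3_sys=[124.0, 126.0, 150.0])
    np.testing.assert_allclose(factor_values(cohort, "blood_pressure"),
                               [122.0, 128.0, 145.0])


def test_subgroup_indices(default_cohort):
    cohort = default_cohort[0]
    assert len(subgroup_indices(cohort, "all")) == len(cohort)
    females = subgroup_indices(cohort, "female")
    assert (cohort.iloc[females]["gender"] == "female").all()
    carriers = subgroup_indices(cohort, "apoe4_carriers")
    assert (cohort.iloc[carriers]["apoe4"] == 1).all()
    matched = subgroup_indices(cohort, "matched_noncarriers")
    assert len(matched) == len(carriers)
    with pytest.raises(ValueError, match="unknown subgroup"):
        subgroup_indices(cohort, "left-handed")


def test_empty_subgroup_rejected():
    cohort = make_cohort_table(genders=["male"] * 12, ages=[70] * 12,
                               fchdr=list(range(12)))
    with pytest.raises(ValueError, match="empty"):
        subgroup_indices(cohort, "female")


def test_factor_battery_signal_tied_to_fchdr(strong_kernel, strong_cohort):
    # images encode only the composite score: its row has the largest r
    K, _ = strong_kernel
    cohort = strong_cohort[0]
    table = run_factor_battery(cohort, K, factors=["fchdr", "age"],
                               subgroup="all", B=19, seed=0)
    table = table.set_index("factor")
    assert table.loc["fchdr", "R"] > table.loc["age", "R"]
    assert table.loc["fchdr", "p_R"] == 0.0  # no permutation reaches it


def test_factor_battery_layout(null_kernel60, null_cohort60):
    K, _ = null_kernel60
    cohort = null_cohort60[0]
    table = run_factor_battery(cohort, K, factors=FACTORS, subgroup="all",
                               B=9, seed=1)
    assert list(table.columns) == ["factor", "subgroup", "n", "R", "p_R",
                                   "MSE", "p_MSE"]
    assert list(table["factor"]) == FACTORS
    assert (table["n"] == len(cohort)).all()
    assert table["MSE"].between(0.4, 2.0).all()


def test_classify_dichotomous_factor_single_class():
    with pytest.raises(ValueError, match="single class"):
        classify_dichotomous_factor(np.eye(12), np.ones(12))


def test_classify_dichotomous_factor_encoded_flag(rng):
    # flag perfectly encoded in one feature -> near-perfect LOO accuracy
    X = 0.1 * rng.normal(size=(24, 6))
    flags = rng.integers(0, 2, 24).astype(bool)
    X[flags, 0] += 4.0
    res = classify_dichotomous_factor(linear_kernel(X), flags)
    assert res.accuracy >= 0.95
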