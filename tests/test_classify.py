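"""SVM classification: dual solution contracts, balanced leave-pair-out CV,
metric arithmetic and the projection-score correlation."""

import numpy as np
import pytest

from riskmvpa.classify import (ClassificationResult, classification_metrics,
                               decision_values, leave_pair_out_cv,
                               loo_classification, metrics_percent,
                               projection_correlation, train_svm)
from riskmvpa.kernels import linear_kernel

# linearly separable toy set used across several checks
SEPARABLE_X = np.array([[-2.0, 0.0], [-1.5, 0.5], [1.5, -0.5], [2.0, 0.0]])
SEPARABLE_Y = np.array([-1, -1, 1, 1])


def test_symmetric_singletons_give_zero_midpoint_decision():
    X = np.array([[-1.0], [1.0]])
    model = train_svm(linear_kernel(X), np.array([-1, 1]), C_param=1000.0)
    mid = decision_values(model, np.array([[0.0, 0.0]]))  # kernel of x=0 vs both
    assert mid[0] == pytest.approx(0.0, abs=1e-6)


def test_label_flip_negates_decision_values():
    K = linear_kernel(SEPARABLE_X)
    m_pos = train_svm(K, SEPARABLE_Y, C_param=10.0)
    m_neg = train_svm(K, -SEPARABLE_Y, C_param=10.0)
    np.testing.assert_allclose(decision_values(m_pos, K),
                               -decision_values(m_neg, K), atol=1e-6)


def test_separable_toy_set_trains_without_errors():
    K = linear_kernel(SEPARABLE_X)
    model = train_svm(K, SEPARABLE_Y, C_param=1000.0)
    f = decision_values(model, K)
    assert (np.sign(f) == SEPARABLE_Y).all()
    # margin support vectors sit at |f| = 1 under the KKT conditions
    on_margin = np.abs(model.dual_coef) < 1000.0 - 1e-6
    assert np.allclose(np.abs(f[model.support[on_margin]]), 1.0, atol=1e-3)


def test_single_class_training_rejected():
    with pytest.raises(ValueError, match="single class"):
        train_svm(np.eye(3), np.array([1, 1, 1]))


def test_zero_kernel_block_returns_bias():
    K = linear_kernel(SEPARABLE_X)
    model = train_svm(K, SEPARABLE_Y)
    f = decision_values(model, np.zeros((3, 4)))
    np.testing.assert_allclose(f, model.bias)


def test_duplicate_test_rows_identical_decisions():
    K = linear_kernel(SEPARABLE_X)
    model = train_svm(K, SEPARABLE_Y)
    block = np.vstack([K[0], K[0]])
    f = decision_values(model, block)
    assert f[0] == f[1]


def test_leave_pair_out_exhaustive_toy():
    # two well-separated pairs: every fold classifies its held-out pair
    X = np.array([[-3.0], [-2.5], [2.5], [3.0]])
    labels = np.array([-1, -1, 1, 1])
    pairs = [(0, 2), (1, 3)]
    res = leave_pair_out_cv(linear_kernel(X), labels, pairs, C_param=10.0)
    assert res.accuracy == 1.0
    assert (np.sign(res.decision[[0, 1]]) == -1).all()
    assert (np.sign(res.decision[[2, 3]]) == 1).all()


def test_no_leakage_from_held_out_labels(strong_kernel, strong_cohort):
    # flipping a held-out subject's stored label must not move its decision
    K, _ = strong_kernel
    cohort = strong_cohort[0]
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(cohort))[:20]
    pairs = [(int(idx[2 * i]), int(idx[2 * i + 1])) for i in range(10)]
    labels = np.zeros(len(cohort), dtype=int)
    for a, b in pairs:
        labels[a], labels[b] = 1, -1
    res = leave_pair_out_cv(K, labels, pairs)
    flipped = labels.copy()
    a0 = pairs[0][0]
    flipped[a0] = -flipped[a0]
    res_flipped = leave_pair_out_cv(K, flipped, pairs)
    assert res.decision[a0] == res_flipped.decision[a0]


def test_overlapping_pairs_rejected():
    with pytest.raises(ValueError, match="disjoint"):
        leave_pair_out_cv(np.eye(4), np.array([1, -1, 1, -1]),
                          [(0, 1), (1, 2)])


def test_metric_arithmetic_reported_percentages():
    acc, sens, spec = classification_metrics(tp=18, fp=7, tn=15, fn=4)
    pct = metrics_percent(acc, sens, spec)
    assert pct == {"accuracy": 75.0, "sensitivity": 81.82, "specificity": 68.18}


def test_metrics_perfect_and_undefined():
    acc, sens, spec = classification_metrics(tp=5, fp=0, tn=7, fn=0)
    assert (acc, sens, spec) == (1.0, 1.0, 1.0)
    acc, sens, spec = classification_metrics(tp=0, fp=2, tn=3, fn=0)
    assert np.isnan(sens) and spec == 0.6  # no positive subjects: undefined


def test_loo_classification_unbalanced_classes():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 5)) * 0.1
    X[:5, 0] += 5.0  # minority class strongly encoded in one feature
    labels = np.array([1] * 5 + [-1] * 15)
    res = loo_classification(linear_kernel(X), labels)
    assert res.accuracy >= 0.9


def _result_from_decision(decision, true):
    pred = np.where(decision >= 0, 1, -1)
    return ClassificationResult(
        true_labels=np.asarray(true), decision=np.asarray(decision, dtype=float),
        predicted=pred, accuracy=float((pred == true).mean()),
        sensitivity=np.nan, specificity=np.nan)


def test_projection_correlation_affine_scores():
    fchdr = np.array([2.0, 5.0, 9.0, 12.0, 15.0])
    res = _result_from_decision(0.3 * fchdr - 2.0, np.array([-1, -1, 1, 1, 1]))
    assert projection_correlation(res, fchdr, "all") == pytest.approx(1.0)


def test_projection_subset_correct_equals_all_when_all_correct():
    fchdr = np.array([2.0, 4.0, 11.0, 14.0])
    res = _result_from_decision(np.array([-2.0, -1.0, 1.0, 2.0]),
                                np.array([-1, -1, 1, 1]))
    assert projection_correlation(res, fchdr, "correct") == \
        projection_correlation(res, fchdr, "all")


def test_projection_constant_vector_undefined():
    fchdr = np.array([2.0, 4.0, 11.0, 14.0])
    res = _result_from_decision(np.ones(4), np.array([1, 1, 1, 1]))
    assert np.isnan(projection_correlation(res, fchdr, "all"))


def test_stored_aggregates_match_recomputation(strong_kernel, strong_cohort):
    from riskmvpa.clinical import match_groups
    K, _ = strong_kernel
    cohort = strong_cohort[0]
    match = match_groups(cohort, "high", "low", 2.0)
    pos = {s: i for i, s in enumerate(cohort["subject_id"])}
    pairs = [(pos[a], pos[b]) for a, b in match.pairs]
    labels = np.zeros(len(cohort), dtype=int)
    for a, b in pairs:
        labels[a], labels[b] = 1, -1
    res = leave_pair_out_cv(K, labels, pairs)
    acc, sens, spec = classification_metrics(*res.confusion())
    assert (acc, sens, spec) == (res.accuracy, res.sensitivity, res.specificity)
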