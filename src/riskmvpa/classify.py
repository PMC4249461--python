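"""Binary risk-group classification on precomputed kernels.

Cross-validation is balanced leave-pair-out: each fold holds out one
matched pair (one subject from each class), trains the soft-margin SVM on
everyone else, and records the held-out decision values.  The lower-risk
class is labeled -1 and the higher-risk class +1, so a positive
cross-validated decision value (the "projection") predicts higher risk.
The projections are also correlated with the continuous FCHDR score,
either over all subjects or over the correctly classified subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

__all__ = ["SVMModel", "ClassificationResult", "train_svm", "decision_values",
           "leave_pair_out_cv", "loo_classification", "classification_metrics",
           "projection_correlation"]

DEFAULT_C = 1.0

#: sentinel for metrics whose denominator is empty
UNDEFINED = float("nan")


@dataclass
class SVMModel:
    """Dual form of a trained soft-margin SVM on a precomputed kernel.

    ``dual_coef`` holds alpha_i * y_i for the support vectors;
    ``support`` indexes them within the training sample.
    """

    dual_coef: np.ndarray
    support: np.ndarray
    bias: float
    C_param: float
    n_train: int

    def __post_init__(self):
        a = self.dual_coef * np.sign(self.dual_coef)  # |alpha|
        if (a < -1e-9).any() or (a > self.C_param + 1e-6).any():
            raise ValueError("dual coefficients violate the box constraint [0, C]")
        if abs(self.dual_coef.sum()) > 1e-6 * max(1.0, a.sum()):
            raise ValueError("dual coefficients do not satisfy sum(alpha_i y_i) = 0")


@dataclass
class ClassificationResult:
    true_labels: np.ndarray
    decision: np.ndarray
    predicted: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    subject_ids: list = field(default_factory=list)

    def confusion(self) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) with +1 the positive (higher-risk) class."""
        t, p = self.true_labels, self.predicted
        return (int(((t == 1) & (p == 1)).sum()), int(((t == -1) & (p == 1)).sum()),
                int(((t == -1) & (p == -1)).sum()), int(((t == 1) & (p == -1)).sum()))


def train_svm(K_train: np.ndarray, labels: np.ndarray,
              C_param: float = DEFAULT_C) -> SVMModel:
    """Solve the soft-margin SVM dual on a precomputed kernel.

    Labels must be -1/+1 with both classes present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    if not set(np.unique(labels)) <= {-1, 1}:
        raise ValueError(f"labels must be -1/+1, got {np.unique(labels)}")
    svc = SVC(kernel="precomputed", C=C_param, tol=1e-4)
    svc.fit(K_train, labels)
    return SVMModel(dual_coef=svc.dual_coef_.ravel().copy(),
                    support=svc.support_.copy(),
                    bias=float(svc.intercept_[0]),
                    C_param=C_param, n_train=K_train.shape[0])


def decision_values(model: SVMModel, K_test_train: np.ndarray) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i K(x, x_i) + b for each test row."""
    K_test_train = np.atleast_2d(np.asarray(K_test_train, dtype=float))
    if K_test_train.shape[1] != model.n_train:
        raise ValueError(
            f"kernel block has {K_test_train.shape[1]} columns, model trained on {model.n_train}")
    return K_test_train[:, model.support] @ model.dual_coef + model.bias


def _predict(decision: np.ndarray) -> np.ndarray:
    # a decision value of exactly 0 is resolved to the positive class
    return np.where(decision >= 0, 1, -1)


def classification_metrics(tp: int, fp: int, tn: int, fn: int
                           ) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as proportions.

    Sensitivity is the proportion of higher-risk (+1) subjects correctly
    classified; specificity the proportion of lower-risk (-1) subjects.
    Empty denominators yield NaN rather than an exception.
    """
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("no counts")
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else UNDEFINED
    spec = tn / (tn + fp) if tn + fp else UNDEFINED
    return acc, sens, spec


def metrics_percent(acc: float, sens: float, spec: float) -> dict:
    """Metrics as percentages rounded to two decimals (reporting format)."""
    return {"accuracy": round(acc * 100, 2), "sensitivity": round(sens * 100, 2),
            "specificity": round(spec * 100, 2)}


def leave_pair_out_cv(K: np.ndarray, labels: np.ndarray, pairs,
                      C_param: float = DEFAULT_C,
                      subject_ids=None, confounds=None) -> ClassificationResult:
    """Balanced cross-validation holding out one matched pair per fold.

    ``pairs`` is a list of (i, j) index pairs partitioning the analysis
    sample; in the unpermuted analysis each pair holds one subject per
    class so every training set stays balanced.  Per-subject decision
    values are retained for the projection analysis.

    If ``confounds`` is given, ``K`` must be the raw kernel and confound
    removal is re-estimated on each fold's training subjects only
    (leakage-free variant); otherwise ``K`` is used as passed (typically
    already confound-removed on the full sample).
    """
    from .kernels import residualize_kernel_blocks

    K = np.asarray(K, dtype=float)
    labels = np.asarray(labels)
    pairs = [tuple(p) for p in pairs]
    idx = sorted({i for p in pairs for i in p})
    if len(idx) != 2 * len(pairs):
        raise ValueError("pairs must be disjoint (each subject in exactly one pair)")
    decision = np.full(K.shape[0], np.nan)
    for i, j in pairs:
        train = [t for t in idx if t not in (i, j)]
        if confounds is not None:
            K_tt, K_st = residualize_kernel_blocks(K, confounds, train, [i, j])
        else:
            K_tt, K_st = K[np.ix_(train, train)], K[np.ix_([i, j], train)]
        model = train_svm(K_tt, labels[train], C_param)
        decision[[i, j]] = decision_values(model, K_st)
    sel = np.array(idx)
    pred = _predict(decision[sel])
    true = labels[sel]
    tp = int(((true == 1) & (pred == 1)).sum())
    fp = int(((true == -1) & (pred == 1)).sum())
    tn = int(((true == -1) & (pred == -1)).sum())
    fn = int(((true == 1) & (pred == -1)).sum())
    acc, sens, spec = classification_metrics(tp, fp, tn, fn)
    full_pred = np.full(K.shape[0], 0)
    full_pred[sel] = pred
    return ClassificationResult(
        true_labels=labels, decision=decision, predicted=full_pred,
        accuracy=acc, sensitivity=sens, specificity=spec,
        subject_ids=list(subject_ids) if subject_ids is not None else [])


def loo_classification(K: np.ndarray, labels: np.ndarray,
                       C_param: float = DEFAULT_C,
                       subject_ids=None) -> ClassificationResult:
    """Leave-one-out classification for possibly unbalanced dichotomous
    targets (e.g. diabetic vs non-diabetic)."""
    K = np.asarray(K, dtype=float)
    labels = np.asarray(labels)
    n = K.shape[0]
    decision = np.empty(n)
    for i in range(n):
        train = [t for t in range(n) if t != i]
        model = train_svm(K[np.ix_(train, train)], labels[train], C_param)
        decision[i] = decision_values(model, K[np.ix_([i], train)])[0]
    pred = _predict(decision)
    tp = int(((labels == 1) & (pred == 1)).sum())
    fp = int(((labels == -1) & (pred == 1)).sum())
    tn = int(((labels == -1) & (pred == -1)).sum())
    fn = int(((labels == 1) & (pred == -1)).sum())
    acc, sens, spec = classification_metrics(tp, fp, tn, fn)
    return ClassificationResult(
        true_labels=labels, decision=decision, predicted=pred,
        accuracy=acc, sensitivity=sens, specificity=spec,
        subject_ids=list(subject_ids) if subject_ids is not None else [])


def projection_correlation(result: ClassificationResult, fchdr: np.ndarray,
                           subset: str = "all") -> float:
    """Pearson correlation between cross-validated decision values and the
    FCHDR score, over all cross-validated subjects or only those correctly
    classified."""
    fchdr = np.asarray(fchdr, dtype=float)
    in_cv = ~np.isnan(result.decision)
    if subset == "all":
        keep = in_cv
    elif subset == "correct":
        keep = in_cv & (result.predicted == result.true_labels)
    else:
        raise ValueError(f"unknown subset {subset!r}; expected 'all' or 'correct'")
    d, f = result.decision[keep], fchdr[keep]
    if keep.sum() < 3:
        raise ValueError("need at least 3 subjects in the subset")
    if np.ptp(d) == 0 or np.ptp(f) == 0:
        return UNDEFINED
    return float(stats.pearsonr(d, f).statistic)
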