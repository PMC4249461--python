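"""Support-vector regression of clinical targets from kernels.

Targets (the composite FCHDR score and single risk factors measured in
heterogeneous units) are z-normalized before regression so that mean
squared errors are comparable across factors: a trivial mean-predictor has
MSE close to 1 on that scale, so values materially below 1 indicate
predictive signal.  Cross-validation is leave-one-out; epsilon-insensitive
SVR runs on the precomputed (confound-removed) kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from . import classify
from .clinical import mean_blood_pressure
from .kernels import confound_design, remove_confounds

__all__ = ["RegressionResult", "znormalize", "loo_svr", "regression_metrics",
           "run_factor_battery", "classify_dichotomous_factor", "FACTORS"]

DEFAULT_C = 1.0
DEFAULT_EPSILON = 0.1

#: single risk factors regressed in the battery, in reporting order
FACTORS = ["fchdr", "blood_pressure", "age", "total_cholesterol",
           "ldl_cholesterol", "smoking_status"]

_FACTOR_COLUMNS = {
    "fchdr": "fchdr",
    "age": "age",
    "total_cholesterol": "total_chol",
    "ldl_cholesterol": "ldl",
    "smoking_status": "smoker",
}

SUBGROUPS = ("all", "female", "male", "apoe4_carriers", "matched_noncarriers")


class DegenerateTargetError(ValueError):
    """Target has no variance, so z-normalization is undefined."""


@dataclass
class RegressionResult:
    true: np.ndarray           # z-normalized targets
    predicted: np.ndarray      # cross-validated predictions, same scale
    r: float
    mse: float
    target_mean: float
    target_sd: float


def znormalize(targets) -> tuple[np.ndarray, float, float]:
    """Center and scale to sample SD 1 (n-1 denominator); returns the
    transform parameters for inversion."""
    t = np.asarray(targets, dtype=float)
    if t.size < 2 or np.ptp(t) == 0:
        raise DegenerateTargetError("target needs at least two distinct values")
    mean, sd = float(t.mean()), float(t.std(ddof=1))
    return (t - mean) / sd, mean, sd


def regression_metrics(true: np.ndarray, predicted: np.ndarray
                       ) -> tuple[float, float]:
    """Pearson r between true and predicted, and the mean squared error on
    the normalized scale.  A constant prediction yields r = NaN (the MSE is
    still returned)."""
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.shape != predicted.shape or true.size < 3:
        raise ValueError("true and predicted must be equal-length vectors (n >= 3)")
    mse = float(np.mean((true - predicted) ** 2))
    if np.ptp(predicted) == 0 or np.ptp(true) == 0:
        return float("nan"), mse
    return float(stats.pearsonr(true, predicted).statistic), mse


def loo_svr(K: np.ndarray, targets, C_param: float = DEFAULT_C,
            epsilon: float = DEFAULT_EPSILON,
            normalize: bool = True, confounds=None) -> RegressionResult:
    """Leave-one-out epsilon-insensitive SVR on a precomputed kernel.

    Targets are z-normalized on the full sample by default (the scale on
    which MSE values are comparable across factors).  If ``confounds`` is
    given, ``K`` must be the raw kernel and confound removal is
    re-estimated on each fold's training subjects only (leakage-free
    variant).
    """
    from .kernels import residualize_kernel_blocks

    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 subjects for leave-one-out SVR, got {n}")
    if normalize:
        y, mean, sd = znormalize(targets)
    else:
        y = np.asarray(targets, dtype=float)
        mean, sd = 0.0, 1.0
    pred = np.empty(n)
    for i in range(n):
        train = np.r_[0:i, i + 1:n]
        if confounds is not None:
            K_tt, K_st = residualize_kernel_blocks(K, confounds, train, [i])
        else:
            K_tt, K_st = K[np.ix_(train, train)], K[np.ix_([i], train)]
        svr = SVR(kernel="precomputed", C=C_param, epsilon=epsilon, tol=1e-4)
        svr.fit(K_tt, y[train])
        pred[i] = svr.predict(K_st)[0]
    r, mse = regression_metrics(y, pred)
    return RegressionResult(true=y, predicted=pred, r=r, mse=mse,
                            target_mean=mean, target_sd=sd)


def factor_values(cohort: pd.DataFrame, factor: str) -> np.ndarray:
    """Extract a battery factor as a numeric target vector.

    'blood_pressure' is the averaged systolic value (first of the three
    readings discarded, mean of the second and third).
    """
    if factor == "blood_pressure":
        return np.array([
            mean_blood_pressure(row)
            for row in cohort[["bp1_sys", "bp2_sys", "bp3_sys"]].to_numpy()])
    col = _FACTOR_COLUMNS.get(factor)
    if col is None or col not in cohort.columns:
        raise KeyError(f"factor {factor!r} not available in cohort table")
    return cohort[col].to_numpy(dtype=float)


def subgroup_indices(cohort: pd.DataFrame, subgroup: str) -> np.ndarray:
    """Row indices (positional) of a named analysis subgroup."""
    if subgroup == "all":
        mask = np.ones(len(cohort), dtype=bool)
    elif subgroup in ("female", "male"):
        mask = (cohort["gender"] == subgroup).to_numpy()
    elif subgroup == "apoe4_carriers":
        mask = (cohort["apoe4"] == 1).to_numpy()
    elif subgroup == "matched_noncarriers":
        from .clinical import match_apoe_noncarriers
        match = match_apoe_noncarriers(cohort)
        chosen = {b for _, b in match.pairs}
        mask = cohort["subject_id"].isin(chosen).to_numpy()
    else:
        raise ValueError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"subgroup {subgroup!r} is empty")
    return idx


def run_factor_battery(cohort: pd.DataFrame, K: np.ndarray,
                       factors=FACTORS, subgroup: str = "all",
                       confound_columns=("apoe4",),
                       C_param: float = DEFAULT_C,
                       epsilon: float = DEFAULT_EPSILON,
                       B: int = 199, seed: int = 0) -> pd.DataFrame:
    """Leave-one-out SVR of each risk factor within one subgroup.

    The kernel is subset to the subgroup and confound removal is re-applied
    within it.  Returns one row per factor with the correlation between
    real and predicted values, the MSE on the normalized scale, and
    permutation p-values for both (B target permutations, p = count/B).
    """
    from .permutation import joint_permutation_test

    idx = subgroup_indices(cohort, subgroup)
    sub = cohort.iloc[idx]
    K_sub = remove_confounds(np.asarray(K)[np.ix_(idx, idx)],
                             confound_design(sub, confound_columns))

    def cv_stats(targets):
        res = loo_svr(K_sub, targets, C_param=C_param, epsilon=epsilon,
                      normalize=False)
        return res.r, res.mse

    rows = []
    for f_i, factor in enumerate(factors):
        try:
            y = factor_values(sub, factor)
        except KeyError:
            continue
        y_norm, _, _ = znormalize(y)
        # one set of permuted CV runs scores both the r null (upper tail)
        # and the MSE null (lower tail)
        perm_r, perm_mse = joint_permutation_test(
            cv_stats, y_norm, B=B, tails=("greater", "less"), seed=seed + f_i)
        rows.append({"factor": factor, "subgroup": subgroup, "n": len(idx),
                     "R": perm_r.observed, "p_R": perm_r.p_value,
                     "MSE": perm_mse.observed, "p_MSE": perm_mse.p_value})
    return pd.DataFrame(rows)


def classify_dichotomous_factor(K: np.ndarray, flags,
                                C_param: float = DEFAULT_C):
    """Leave-one-out classification of a dichotomous factor (e.g. diabetic
    vs non-diabetic); classes may be unbalanced, so accuracy is interpreted
    against the majority-class rate."""
    flags = np.asarray(flags)
    labels = np.where(flags.astype(bool), 1, -1)
    if len(np.unique(labels)) < 2:
        raise ValueError("dichotomous factor has a single class")
    return classify.loo_classification(np.asarray(K, dtype=float), labels,
                                       C_param=C_param)
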