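"""Linear kernels over voxel features and kernel-level confound removal.

Confounds are removed with the residual-forming projector
``R = I - C (C'C)^- C'`` applied symmetrically to the Gram matrix,
``K -> R K R``, which is exactly the linear kernel of the residualized
features ``R X``.  The confound design always carries an intercept so that
removal also centers the kernel; by default the only substantive covariate
is APOE epsilon-4 carriership.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["linear_kernel", "residual_matrix", "remove_confounds",
           "confound_design", "residualize_kernel_blocks", "check_kernel"]

PSD_TOL = 1e-8


def linear_kernel(X: np.ndarray) -> np.ndarray:
    """Gram matrix of subject rows: K[i, j] = <x_i, x_j>."""
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    K = X @ X.T
    return (K + K.T) / 2.0


def confound_design(cohort: pd.DataFrame, columns=("apoe4",),
                    include_intercept: bool = True) -> np.ndarray:
    """Build an n x p confound design from cohort columns, with intercept."""
    cols = [np.ones(len(cohort))] if include_intercept else []
    cols += [cohort[c].to_numpy(dtype=float) for c in columns]
    if not cols:
        return np.empty((len(cohort), 0))
    return np.column_stack(cols)


def residual_matrix(C: np.ndarray) -> np.ndarray:
    """Residual-forming projector R = I - C (C'C)^- C'.

    Rank-deficient designs are handled by the Moore-Penrose pseudoinverse.
    R is symmetric, idempotent and annihilates the column span of C.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.ndim != 2:
        raise ValueError(f"confound design must be 2-D, got shape {C.shape}")
    if C.shape[1] == 0:
        return np.eye(n)
    if n < C.shape[1]:
        raise ValueError(f"need n >= p, got n={n}, p={C.shape[1]}")
    R = np.eye(n) - C @ np.linalg.pinv(C)
    return (R + R.T) / 2.0


def remove_confounds(K: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Project confound effects out of a kernel: returns R K R."""
    K = np.asarray(K, dtype=float)
    if C is None or np.asarray(C).shape[-1] == 0:
        return K
    C = np.asarray(C, dtype=float)
    if C.shape[0] != K.shape[0]:
        raise ValueError(
            f"confound rows ({C.shape[0]}) must match kernel size ({K.shape[0]})")
    R = residual_matrix(C)
    out = R @ K @ R
    return (out + out.T) / 2.0


def residualize_kernel_blocks(K: np.ndarray, C: np.ndarray,
                              train_idx, test_idx
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Train-only confound removal on kernel blocks.

    The projector is estimated on the training subjects alone and applied
    to both the train/train block and the test/train block, so no test
    information enters the residualization:

        K'_tt = R_t K_tt R_t
        K'_st = (K_st - C_s C_t^+ K_tt) R_t

    which equals the Gram blocks of the features residualized against the
    confound fit on the training subjects only.  This is the leakage-free
    alternative to applying one full-sample projector to the whole kernel.
    """
    K = np.asarray(K, dtype=float)
    C = np.asarray(C, dtype=float)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    Ct, Cs = C[train_idx], C[test_idx]
    Rt = residual_matrix(Ct)
    K_tt = K[np.ix_(train_idx, train_idx)]
    K_st = K[np.ix_(test_idx, train_idx)]
    K_tt_res = Rt @ K_tt @ Rt
    K_st_res = (K_st - Cs @ np.linalg.pinv(Ct) @ K_tt) @ Rt
    return (K_tt_res + K_tt_res.T) / 2.0, K_st_res


def check_kernel(K: np.ndarray, tol: float = PSD_TOL) -> None:
    """Validate symmetry and positive semidefiniteness of a kernel."""
    K = np.asarray(K)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"kernel must be square, got shape {K.shape}")
    asym = np.abs(K - K.T).max()
    if asym > tol:
        raise ValueError(f"kernel asymmetric (max deviation {asym:g})")
    scale = max(1.0, float(np.abs(K).max()))
    w = np.linalg.eigvalsh((K + K.T) / 2.0)
    if w.min() < -tol * scale * K.shape[0]:
        raise ValueError(f"kernel not positive semidefinite (min eigenvalue {w.min():g})")


def save_kernel(K: np.ndarray, subject_ids, path) -> None:
    pd.DataFrame(K, index=subject_ids, columns=subject_ids).to_csv(path, sep="\t")


def load_kernel(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str))
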