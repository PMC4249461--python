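"""Permutation significance testing for cross-validated statistics.

The null distribution is built by randomly exchanging the labels (or
continuous targets) across subjects and re-running the complete
cross-validated pipeline for each permutation; the kernel and the confound
design stay fixed.  The p-value is the proportion of permuted statistics at
or beyond the observed one: count / B, reported as "<= 1/B" when the count
is zero.  An add-one correction ((count+1)/(B+1)) is available behind a
flag but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PermutationResult", "permutation_test", "joint_permutation_test",
           "permuted_statistic_summary"]


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    B: int
    seed: int
    tail: str
    add_one: bool = False

    @property
    def p_label(self) -> str:
        """Reporting form: '<= 1/B' when no permutation reached the observed
        statistic, otherwise the proportion itself."""
        if not self.add_one and self.p_value == 0.0:
            return f"<= {1.0 / self.B:g}"
        return f"{self.p_value:g}"


def _p_from_counts(count: int, B: int, add_one: bool) -> float:
    return (count + 1) / (B + 1) if add_one else count / B


def joint_permutation_test(statistic_fn, values, B: int, tails,
                           seed: int = 0, add_one: bool = False
                           ) -> list[PermutationResult]:
    """Permutation test for several statistics sharing one set of permuted
    pipeline runs.

    ``statistic_fn(values) -> tuple of reals`` re-runs the complete
    cross-validated analysis; ``tails`` gives one of {'greater', 'less'}
    per returned statistic ('greater' for accuracy and r, 'less' for MSE).
    """
    if B < 1:
        raise ValueError(f"need at least one permutation, got B={B}")
    tails = list(tails)
    for t in tails:
        if t not in ("greater", "less"):
            raise ValueError(f"unknown tail {t!r}; expected 'greater' or 'less'")
    values = np.asarray(values)
    rng = np.random.default_rng(seed)
    observed = np.asarray(statistic_fn(values), dtype=float).ravel()
    if observed.size != len(tails):
        raise ValueError("statistic_fn arity does not match the tails given")
    permuted = np.empty((B, observed.size))
    for b in range(B):
        permuted[b] = np.asarray(
            statistic_fn(values[rng.permutation(len(values))]), dtype=float).ravel()
    results = []
    for k, tail in enumerate(tails):
        if tail == "greater":
            count = int((permuted[:, k] >= observed[k]).sum())
        else:
            count = int((permuted[:, k] <= observed[k]).sum())
        results.append(PermutationResult(
            observed=float(observed[k]), permuted=permuted[:, k].copy(),
            p_value=_p_from_counts(count, B, add_one), B=B, seed=seed,
            tail=tail, add_one=add_one))
    return results


def permutation_test(statistic_fn, values, B: int, tail: str = "greater",
                     seed: int = 0, add_one: bool = False) -> PermutationResult:
    """Single-statistic permutation test (see joint_permutation_test)."""
    return joint_permutation_test(lambda v: (statistic_fn(v),), values, B,
                                  (tail,), seed=seed, add_one=add_one)[0]


def permuted_statistic_summary(result: PermutationResult) -> tuple[float, float]:
    """Mean and SD of the permuted null distribution, for calibration
    reporting (a balanced null classification should average near 0.5)."""
    if result.B < 2:
        raise ValueError("need at least two permutations to summarize")
    return float(result.permuted.mean()), float(result.permuted.std(ddof=1))
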