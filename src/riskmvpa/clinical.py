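"""Clinical derivations: diabetes status, blood-pressure averaging,
Framingham risk-group stratification, covariate matching and a
Hardy-Weinberg equilibrium check.

Risk groups follow the gender-specific integer cutoffs used to stratify
Framingham coronary heart disease risk (FCHDR) scores in elderly cohorts:

    ========  ============  ==============
    group     male          female
    ========  ============  ==============
    low       score <= 5    score <= 9
    medium    5 < s <= 8    9 < s <= 14
    high      score > 8     score > 14
    ========  ============  ==============

The composite FCHDR score itself is an input column, not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["diabetes_status", "mean_blood_pressure", "risk_group",
           "risk_groups", "match_groups", "match_apoe_noncarriers",
           "hardy_weinberg_test", "MatchResult"]

#: fasting glucose (mg/dl) at or above which diabetes mellitus is assigned
DIABETES_GLUCOSE_THRESHOLD = 126.0

RISK_CUTOFFS = {"male": (5, 8), "female": (9, 14)}


class MissingDataError(ValueError):
    pass


def diabetes_status(glucose: float, hypoglycemic_meds: bool) -> bool:
    """Diabetes mellitus: fasting glucose >= 126 mg/dl and/or current use of
    insulin or oral hypoglycemic treatment."""
    if glucose is None or (isinstance(glucose, float) and np.isnan(glucose)):
        if hypoglycemic_meds:
            return True
        raise MissingDataError("glucose missing and no medication flag set")
    if glucose <= 0:
        raise ValueError(f"glucose must be positive, got {glucose}")
    return bool(glucose >= DIABETES_GLUCOSE_THRESHOLD or hypoglycemic_meds)


def mean_blood_pressure(readings) -> float:
    """Arterial pressure value from three ordered readings: the first
    measurement is discarded and the arithmetic mean of the second and
    third is returned."""
    readings = list(readings)
    if len(readings) != 3 or any(r is None or np.isnan(r) for r in readings):
        raise MissingDataError(f"exactly three readings required, got {readings}")
    return (readings[1] + readings[2]) / 2.0


def risk_group(fchdr: int, gender: str) -> str:
    """Assign 'low' / 'medium' / 'high' from the gender-specific cutoffs.

    Boundary scores belong to the lower group (cutoffs are inclusive
    upper bounds)."""
    if gender not in RISK_CUTOFFS:
        raise ValueError(f"unknown gender {gender!r}; expected 'male' or 'female'")
    if fchdr < 0:
        raise ValueError(f"FCHDR score must be >= 0, got {fchdr}")
    lo, hi = RISK_CUTOFFS[gender]
    if fchdr <= lo:
        return "low"
    if fchdr <= hi:
        return "medium"
    return "high"


def risk_groups(cohort: pd.DataFrame) -> pd.Series:
    """Vectorized risk_group over a cohort table."""
    return pd.Series(
        [risk_group(s, g) for s, g in zip(cohort["fchdr"], cohort["gender"])],
        index=cohort.index, name="risk_group")


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]        # (subject_id in a, subject_id in b)
    discarded: list[str]
    warnings: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _greedy_pairs(a: pd.DataFrame, b: pd.DataFrame, caliper: float
                  ) -> list[tuple[str, str]]:
    """Greedy nearest-age matching within one gender; each subject used at
    most once, ties broken by subject_id order."""
    cands = []
    for _, ra in a.iterrows():
        for _, rb in b.iterrows():
            d = abs(ra["age"] - rb["age"])
            if d <= caliper:
                cands.append((d, ra["subject_id"], rb["subject_id"]))
    cands.sort()
    used_a, used_b, pairs = set(), set(), []
    for _, ia, ib in cands:
        if ia not in used_a and ib not in used_b:
            pairs.append((ia, ib))
            used_a.add(ia)
            used_b.add(ib)
    return pairs


def match_groups(cohort: pd.DataFrame, group_a: str, group_b: str,
                 age_caliper: float = 2.0) -> MatchResult:
    """Match subjects across two risk groups by gender and age.

    Greedy nearest-age pairing within each gender with an age caliper;
    returns matched (a, b) subject-id pairs plus the discarded subjects.
    An infeasible matching yields an empty pair list, not an error.
    """
    groups = risk_groups(cohort)
    a = cohort[groups == group_a]
    b = cohort[groups == group_b]
    if a.empty or b.empty:
        raise ValueError(f"risk groups {group_a!r}/{group_b!r} must both be non-empty")
    pairs: list[tuple[str, str]] = []
    for gender in ("female", "male"):
        pairs.extend(_greedy_pairs(a[a["gender"] == gender],
                                   b[b["gender"] == gender], age_caliper))
    matched = {s for p in pairs for s in p}
    discarded = [s for s in pd.concat([a, b])["subject_id"] if s not in matched]
    return MatchResult(pairs=pairs, discarded=discarded, warnings=[])


def match_apoe_noncarriers(cohort: pd.DataFrame, carriers=None) -> MatchResult:
    """Select one non-carrier per APOE4 carrier, matched on gender and, as
    closely as possible, age and FCHDR score (age first, score as tiebreak).

    Returns carrier/non-carrier pairs; if the non-carrier pool cannot cover
    every carrier the match is partial and a warning is recorded.
    """
    if carriers is None:
        carriers = set(cohort.loc[cohort["apoe4"] == 1, "subject_id"])
    carriers = set(carriers)
    carr = cohort[cohort["subject_id"].isin(carriers)]
    pool = cohort[(cohort["apoe4"] == 0) & ~cohort["subject_id"].isin(carriers)]
    pairs, warnings = [], []
    used = set()
    for _, rc in carr.sort_values("subject_id").iterrows():
        best = None
        for _, rp in pool[pool["gender"] == rc["gender"]].iterrows():
            if rp["subject_id"] in used:
                continue
            key = (abs(rc["age"] - rp["age"]),
                   abs(rc["fchdr"] - rp["fchdr"]), rp["subject_id"])
            if best is None or key < best[0]:
                best = (key, rp["subject_id"])
        if best is None:
            warnings.append(f"no available non-carrier match for {rc['subject_id']}")
            continue
        used.add(best[1])
        pairs.append((rc["subject_id"], best[1]))
    return MatchResult(pairs=pairs, discarded=[], warnings=warnings)


def balanced_split_pairs(cohort: pd.DataFrame) -> tuple[list[tuple[str, str]], pd.Series]:
    """Partition a cohort into same-gender, adjacent-age subject pairs with
    one +1 and one -1 label per pair (exactly balanced classes).

    Used for null-calibration analyses where the class assignment is
    arbitrary by construction: the pairing fixes the balanced leave-pair-out
    fold structure, labels are then permuted.  With an odd within-gender
    count the leftover subject is dropped.
    """
    ordered = cohort.sort_values(["gender", "age", "subject_id"])
    pairs: list[tuple[str, str]] = []
    for _, grp in ordered.groupby("gender", sort=True):
        ids = list(grp["subject_id"])
        pairs.extend((ids[2 * i], ids[2 * i + 1]) for i in range(len(ids) // 2))
    labels = pd.Series(0, index=cohort["subject_id"].to_numpy(), name="label")
    for a, b in pairs:
        labels[a], labels[b] = 1, -1
    return pairs, labels


def hardy_weinberg_test(n_hom_e4: int, n_het_e4: int, n_other: int
                        ) -> tuple[float, float]:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg equilibrium
    for a biallelic locus, from genotype counts
    (e4/e4 homozygotes, e4 heterozygotes, non-carriers).

    Expected counts come from the estimated allele frequency
    p = (2*hom + het) / (2*N) via (p^2, 2pq, q^2)*N.  A monomorphic sample
    fits equilibrium exactly (statistic 0).
    """
    counts = np.array([n_hom_e4, n_het_e4, n_other], dtype=float)
    if (counts < 0).any():
        raise ValueError(f"genotype counts must be >= 0, got {counts}")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p ** 2, 2 * p * q, q ** 2])
    nz = expected > 0
    chi2 = float(((counts[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))
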