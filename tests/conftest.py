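import numpy as np
import pandas as pd
import pytest

from riskmvpa import imaging, kernels
from riskmvpa.synthetic import (SyntheticConfig, generate_cohort,
                                generate_null_cohort, strong_signal_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Mixed-gender cohort at the default study conditions."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def strong_cohort():
    """Female-only strong-signal cohort used for signal-recovery checks."""
    return generate_cohort(strong_signal_config(seed=3))


@pytest.fixture(scope="session")
def strong_kernel(strong_cohort):
    cohort, images, _ = strong_cohort
    feats = imaging.vectorize(images, imaging.build_mask(images))
    K = kernels.remove_confounds(kernels.linear_kernel(feats),
                                 kernels.confound_design(cohort))
    return K, feats


@pytest.fixture(scope="session")
def null_cohort60():
    """Cohort whose images carry no information about any clinical column."""
    return generate_null_cohort(SyntheticConfig(n_subjects=60, seed=11))


@pytest.fixture(scope="session")
def null_kernel60(null_cohort60):
    cohort, images = null_cohort60
    feats = imaging.vectorize(images, imaging.build_mask(images))
    K = kernels.remove_confounds(kernels.linear_kernel(feats),
                                 kernels.confound_design(cohort))
    return K, feats


def make_cohort_table(genders, ages, fchdr, **extra):
    """Hand-built minimal cohort table for matching/grouping tests."""
    n = len(genders)
    base = {
        "subject_id": [f"T{i:03d}" for i in range(n)],
        "gender": list(genders),
        "age": list(ages),
        "fchdr": list(fchdr),
        "glucose": [100.0] * n,
        "hypoglycemic_meds": [0] * n,
        "bp1_sys": [130.0] * n,
        "bp2_sys": [125.0] * n,
        "bp3_sys": [123.0] * n,
        "total_chol": [200.0] * n,
        "hdl": [50.0] * n,
        "ldl": [120.0] * n,
        "smoker": [0] * n,
        "apoe4": [0] * n,
    }
    base.update(extra)
    return pd.DataFrame(base)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
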