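"""Synthetic cohort generator: clinical tables plus gray-matter image stacks.

Emulates the statistical structure the downstream decoding analyses assume:
an elderly cohort (ages 66-75) with gender-specific Framingham coronary
heart disease risk (FCHDR) scores spanning all three risk strata, single
cardiovascular risk factors mildly correlated with the composite score, an
APOE epsilon-4 carrier flag, and smooth 3-D gray-matter probability maps in
which expression of a spatially contiguous voxel pattern *decreases* with
the risk score (gray-matter loss with rising cardiovascular risk).  The
signal slope is gender-specific (default: present in females, absent in
males) and amplified in APOE4 carriers.

No attempt is made to simulate realistic neuroanatomy, registration, or
scanner artifacts; images are smooth random fields on a small grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import GMImageSet

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_cohort",
           "generate_null_cohort", "strong_signal_config"]

#: column order of the cohort table (shared with the clinical module)
COHORT_COLUMNS = [
    "subject_id", "gender", "age", "fchdr", "glucose", "hypoglycemic_meds",
    "bp1_sys", "bp2_sys", "bp3_sys", "total_chol", "hdl", "ldl",
    "smoker", "apoe4",
]


class ConfigurationError(ValueError):
    """A synthetic-cohort parameter is outside its admissible range."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated study.

    Effect sizes are in gray-matter probability units per within-cohort
    standard deviation of the FCHDR score; ``noise_sd`` is the standard
    deviation of the spatially smooth per-subject noise field after
    smoothing.  ``pattern_sparsity`` is the fraction of in-grid voxels
    carrying signal, laid out as contiguous blobs.
    """

    n_subjects: int = 120
    image_shape: tuple[int, int, int] = (12, 14, 12)
    female_fraction: float = 0.5
    effect_size_female: float = 0.06
    effect_size_male: float = 0.0
    apoe_prevalence: float = 0.22
    apoe_effect_multiplier: float = 0.5
    noise_sd: float = 0.03
    pattern_sparsity: float = 0.05
    smooth_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ConfigurationError(f"n_subjects must be >= 4, got {self.n_subjects}")
        if len(self.image_shape) != 3 or any(d < 4 for d in self.image_shape):
            raise ConfigurationError(f"image_shape dims must all be >= 4, got {self.image_shape}")
        for name in ("female_fraction", "apoe_prevalence", "pattern_sparsity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.apoe_effect_multiplier < 0:
            raise ConfigurationError(
                f"apoe_effect_multiplier must be >= 0, got {self.apoe_effect_multiplier}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.smooth_sigma <= 0:
            raise ConfigurationError(f"smooth_sigma must be > 0, got {self.smooth_sigma}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated cohort."""

    weight_pattern: np.ndarray          # 3-D grid of signal loadings
    latent_score: np.ndarray            # standardized FCHDR per subject
    realized_effect: np.ndarray         # slope actually applied per subject
    signal_voxels: np.ndarray = field(default=None)  # flat indices, set in __post_init__

    def __post_init__(self):
        if self.signal_voxels is None:
            self.signal_voxels = np.flatnonzero(self.weight_pattern.ravel())


def strong_signal_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Female-only cohort at the default (female) effect size.

    With the default male slope at zero, a mixed cohort carries signal in
    only half its subjects; the all-female variant is the configuration
    used for signal-recovery checks.
    """
    params = dict(n_subjects=120, female_fraction=1.0, seed=seed)
    params.update(overrides)
    return SyntheticConfig(**params)


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-blurred white noise rescaled to zero mean, unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / f.std()


def _contiguous_pattern(rng: np.random.Generator, shape, sparsity: float) -> np.ndarray:
    """Binary loading grid: exactly round(sparsity * n_voxels) voxels, laid
    out as compact blobs around a few random centers."""
    n_vox = int(np.prod(shape))
    k = int(round(sparsity * n_vox))
    grid = np.zeros(shape)
    if k == 0:
        return grid
    n_blobs = max(1, min(3, k // 20))
    centers = np.column_stack(
        [rng.integers(1, d - 1, size=n_blobs) for d in shape]).astype(float)
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    # distance to nearest blob center; k smallest distances form the pattern
    d = np.min(np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2), axis=1)
    order = np.lexsort((np.arange(n_vox), d))
    grid.ravel()[order[:k]] = 1.0
    return grid


def _draw_clinical(rng: np.random.Generator, cfg: SyntheticConfig) -> pd.DataFrame:
    n = cfg.n_subjects
    female = rng.random(n) < cfg.female_fraction
    gender = np.where(female, "female", "male")
    age = rng.integers(66, 76, size=n)
    apoe4 = (rng.random(n) < cfg.apoe_prevalence).astype(int)

    # gender-specific integer scores placed so that the Table-1 style
    # cutoffs populate all three risk strata for moderate n
    center = np.where(female, 11.5, 6.5)
    fchdr = np.clip(np.round(center + 3.5 * rng.standard_normal(n)), 0, None).astype(int)
    z = (fchdr - fchdr.mean()) / fchdr.std(ddof=1)

    # single risk factors: plausible adult ranges, mildly loaded on the score
    glucose = np.clip(np.round(95 + 12 * z + 18 * rng.standard_normal(n)), 60, None)
    meds = (rng.random(n) < 0.08).astype(int)
    bp_base = 125 + 8 * z + 12 * rng.standard_normal(n)
    bp1 = np.round(bp_base + 5 + 4 * rng.standard_normal(n))  # first reading runs high
    bp2 = np.round(bp_base + 4 * rng.standard_normal(n))
    bp3 = np.round(bp_base + 4 * rng.standard_normal(n))
    total_chol = np.clip(np.round(205 + 10 * z + 30 * rng.standard_normal(n)), 100, None)
    hdl = np.clip(np.round(52 - 3 * z + 10 * rng.standard_normal(n)), 20, None)
    ldl = np.clip(np.round(0.62 * total_chol + 10 * rng.standard_normal(n)), 40, None)
    smoker = (rng.random(n) < np.clip(0.15 + 0.05 * z, 0.02, 0.6)).astype(int)

    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "gender": gender, "age": age, "fchdr": fchdr,
        "glucose": glucose, "hypoglycemic_meds": meds,
        "bp1_sys": bp1, "bp2_sys": bp2, "bp3_sys": bp3,
        "total_chol": total_chol, "hdl": hdl, "ldl": ldl,
        "smoker": smoker, "apoe4": apoe4,
    })[COHORT_COLUMNS]


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[pd.DataFrame, GMImageSet, SyntheticTruth]:
    """Simulate a cohort table, its gray-matter image stack, and the truth.

    Each subject's image is a shared smooth baseline template minus a
    gender- and APOE4-scaled multiple of the standardized FCHDR score
    along the planted weight pattern, plus smooth noise, clipped to [0, 1].
    Deterministic given the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort = _draw_clinical(rng, config)
    shape = tuple(config.image_shape)

    baseline = 0.5 + 0.12 * _smooth_unit_field(rng, shape, config.smooth_sigma)
    pattern = _contiguous_pattern(rng, shape, config.pattern_sparsity)

    z = (cohort["fchdr"] - cohort["fchdr"].mean()).to_numpy() / cohort["fchdr"].std(ddof=1)
    slope = np.where(cohort["gender"] == "female",
                     config.effect_size_female, config.effect_size_male)
    slope = slope * (1.0 + config.apoe_effect_multiplier * cohort["apoe4"].to_numpy())

    data = np.empty((config.n_subjects,) + shape)
    for i in range(config.n_subjects):
        noise = (config.noise_sd * _smooth_unit_field(rng, shape, config.smooth_sigma)
                 if config.noise_sd > 0 else 0.0)
        data[i] = baseline - slope[i] * z[i] * pattern + noise
    np.clip(data, 0.0, 1.0, out=data)

    images = GMImageSet(data=data, affine=np.eye(4),
                        subject_ids=list(cohort["subject_id"]))
    truth = SyntheticTruth(weight_pattern=pattern, latent_score=z,
                           realized_effect=slope * z)
    return cohort, images, truth


def generate_null_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GMImageSet]:
    """Same generative process with both effect sizes forced to zero: the
    images carry no information about the score (or any clinical column)."""
    null_cfg = SyntheticConfig(**{**config.__dict__,
                                  "effect_size_female": 0.0,
                                  "effect_size_male": 0.0})
    cohort, images, _ = generate_cohort(null_cfg)
    return cohort, images


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
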