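# Methods

## Decoding model

The package treats each subject's gray-matter probability map as a point
in voxel space and fits kernel machines on the linear Gram matrix of the
masked maps. With n subjects ≪ voxels, the linear kernel is the standard
choice for voxel-level morphometry and is required for exact primal
weight recovery; no nonlinear kernels are offered. Classification is the
soft-margin SVM dual on the precomputed kernel (scikit-learn's libsvm
backend, solver tolerance 1e−4); regression is ε-insensitive SVR on the
same kernel. Both are deterministic given the kernel, labels and
hyperparameters.

### Confound removal

Confounds are removed at the kernel level with the residual-forming
projector R = I − C(CᵀC)⁻Cᵀ (pseudoinverse, so rank-deficient designs are
safe), applied symmetrically: K → R K R. This is algebraically identical
to residualizing each voxel column of X against C and recomputing the
kernel; the test suite checks that identity against the explicit Gram
matrix of R·X. The design C always carries an intercept — without it the
projector does not remove mean offsets — plus the APOE ε4 indicator by
default.

Two removal scopes exist:

- **full-sample** (default): one projector estimated on all subjects and
  applied once to the whole kernel. This mirrors the classical practice
  of applying "a residual form matrix to the kernels", but mixes test
  information into the training blocks.
- **train-only** (`confounds=` on `leave_pair_out_cv` / `loo_svr`): the
  projector is re-estimated on each fold's training subjects and applied
  to the train/train and test/train blocks
  (K′_st = (K_st − C_s C_t⁺ K_tt) R_t), so no test subject influences the
  residualization.

The difference matters in one identifiable regime: when the prediction
target coincides with a removed confound, full-sample removal forces each
group's residuals to sum to zero, so every held-out subject
anti-correlates with its own class and leave-pair-out accuracy collapses
to 0 rather than 0.5. The train-only variant restores chance-level
behavior and is the right scope for confound-annihilation checks; for
ordinary targets the two differ negligibly at cohort scale.

### Cross-validation

Classification uses balanced leave-pair-out: groups are first matched by
gender and age (greedy nearest-age within gender, caliper 2 years by
default, ties broken by subject id; greedy rather than optimal matching
keeps the procedure reproducible and is adequate at cohort scale — an
exhaustive variant would change pair counts only marginally). Each fold
holds out one matched pair, keeping every training set balanced.
Regression uses leave-one-out. Cross-validated decision values are
retained per subject; the "projection" analysis correlates them with the
continuous FCHDR score, reported both over all subjects and over the
correctly classified subset (the two conventions in circulation; both are
computed rather than guessing one).

### Permutation inference

p = (# permuted statistics at or beyond observed)/B, with the complete
cross-validated pipeline re-run per shuffle; the kernel and confound
design stay fixed, only labels/targets are exchanged, unstratified.
Upper tail for accuracy and r, lower tail for MSE; a zero count is
reported as "≤ 1/B". The (count+1)/(B+1) correction is available behind
`add_one` but off by default. B defaults to 1000 in the pipeline;
analysis drivers use B = 199 and the test suite B = 99–200 (problem sizes
chosen so the whole battery runs on a single CPU in minutes). Regression
r and MSE share one set of permuted runs.

## Clinical derivations

Diabetes: fasting glucose ≥ 126 mg/dl and/or current hypoglycemic
treatment. Blood pressure: first of three readings discarded, mean of the
second and third (the "blood pressure" battery factor is this systolic
average; diastolic would be configurable but systolic follows the
Framingham convention). Risk strata: male ≤5 low, ≤8 medium, >8 high;
female ≤9 / ≤14 / >14 — boundaries inclusive in the lower group. The
composite FCHDR score itself is an input: the gender-specific point
tables that produce it are not part of the package. Hardy–Weinberg
equilibrium is checked by the standard 1-df chi-square of genotype counts
against p², 2pq, q² at the estimated allele frequency; a monomorphic
sample scores 0.

z-normalization of regression targets (including FCHDR) uses the full
sample, which keeps MSE comparable across factors; a fold-wise option
would avoid the (tiny) leakage but break that comparability.

## Synthetic cohort generator

The generator emulates the statistical structure of an elderly
cardiovascular-risk cohort, not its anatomy:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 120 | cohort size |
| image_shape | 12×14×12 | voxel grid |
| female_fraction | 0.5 | gender mix |
| effect_size_female | 0.06 | GM units per score SD (female slope) |
| effect_size_male | 0.0 | male slope (gender dissociation) |
| apoe_prevalence | 0.22 | carrier fraction |
| apoe_effect_multiplier | 0.5 | slope amplification in carriers |
| noise_sd | 0.03 | SD of smooth per-subject noise |
| pattern_sparsity | 0.05 | fraction of voxels carrying signal |
| smooth_sigma | 2.0 | Gaussian blur width, voxels |

Ages are integer-uniform on [66, 75]. Integer FCHDR scores are drawn per
gender (males centered near 6.5, females near 11.5, SD 3.5, clipped at 0)
so all three risk strata are populated at moderate n. Single risk factors
get plausible adult ranges with mild positive loadings on the
standardized score. Images are a shared smooth baseline template minus
slope(gender) × (1 + multiplier × APOE4) × standardized score along a
contiguous blob pattern (exactly round(sparsity × n_voxels) voxels around
up to three random centers), plus smooth noise, clipped to [0, 1].
Signal direction is gray-matter *loss* with rising risk, keeping
weight-map signs interpretable. Smoothness is a fixed-width Gaussian blur
of white noise (σ = 2 voxels), a toy-scale stand-in for 8 mm FWHM
smoothing; noise_sd is the SD *after* smoothing. The female-only
`strong_signal_config` is the signal-recovery condition used in tests.

The effect sizes are free parameters — no published effect-size estimate
for the cardiovascular-risk–gray-matter association exists to calibrate
them — chosen once so that the strong-signal condition is comfortably
decodable and the default mixed cohort shows the female-significant /
male-null dissociation.

What passing tests show: the pipeline recovers planted linear signal,
its permutation machinery is calibrated, and its algebra is exact. What
they do not show: performance on real morphometry, where registration
error, anatomical covariance, scanner effects and non-linear
confound–signal entanglement are all absent from the generator.

### Numerical choices and degenerate inputs

- SVM/SVR: C = 1, ε = 0.1, solver tolerance 1e−4 (hyperparameters fixed,
  no inner tuning loop; configurable and echoed in outputs).
- Decision value exactly 0 predicts +1 (deterministic tie-break).
- Mask: voxels at exactly the 0.15 threshold are kept ("less than 15%"
  is discarded); the common mask uses the across-subject mean by default,
  with an all-subjects rule available — "discarded in all images" slightly
  favors the latter, but it is brittle to a single outlier subject, so
  both are exposed.
- Kernels are symmetrized and PSD-checked to 1e−8; empty confound designs
  return K unchanged; constant targets raise a degenerate-target error;
  zero-denominator sensitivity/specificity/r return NaN markers, not
  exceptions.
- Everything is seeded through `numpy.random.default_rng`; identical
  config + seed is bit-identical end to end.

## Limitations

- No multiclass classification; group contrasts are binary pairs.
- No multiple-testing correction across the factor battery (by design;
  consumers should correct when reading the battery table).
- Matching is greedy; published pair counts from any specific study
  cannot be reproduced exactly without that study's matching procedure.
- The weight map is descriptive: no thresholding, no anatomical labels,
  no voxel-wise inference.
- Combined APOE ε2/ε4 genotype effects are not modeled.
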