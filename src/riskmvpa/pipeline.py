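"""Configuration-driven orchestration of the full analysis battery.

A run reproduces, on a given cohort (real files or a synthetic
configuration), the study sequence: risk-group classification on matched
pairs, support-vector regression of the composite risk score, the
single-factor battery, gender-split and APOE4-split regressions,
dichotomous diabetes classification, and weight-map export.  Every stage
writes structured outputs (JSON + delimited tables + NIfTI) under the
output directory, along with a config echo and a run log sufficient to
reproduce the run exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import classify, clinical, imaging, kernels, regress, synthetic, weights
from .permutation import permutation_test
from .synthetic import SyntheticConfig

ALL_ANALYSES = ("classify-pairs", "regress-fchdr", "regress-factors",
                "regress-by-gender", "regress-apoe-split", "diabetes-classify",
                "weights")

PAIRED_COMPARISONS = (("medium", "low"), ("high", "medium"), ("high", "low"))


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str = "results/run"
    cohort_path: str | None = None       # delimited cohort table
    image_paths: list[str] | None = None  # per-subject NIfTI files
    synthetic: SyntheticConfig | None = None  # used when no paths are given
    analyses: tuple[str, ...] = ALL_ANALYSES
    mask_threshold: float = imaging.DEFAULT_GM_THRESHOLD
    mask_rule: str = "mean"
    age_caliper: float = 2.0
    svm_c: float = classify.DEFAULT_C
    svr_c: float = regress.DEFAULT_C
    svr_epsilon: float = regress.DEFAULT_EPSILON
    confound_columns: tuple[str, ...] = ("apoe4",)
    B: int = 1000
    p_correction: str = "none"           # {"none", "add-one"}
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; choose from {ALL_ANALYSES}")
        if self.p_correction not in ("none", "add-one"):
            raise ValueError(f"p_correction must be 'none' or 'add-one', got {self.p_correction!r}")
        if self.cohort_path is None and self.synthetic is None:
            raise ValueError("either cohort/image paths or a synthetic config is required")


@dataclass
class PipelineData:
    """Loaded or simulated inputs shared by all stages."""

    cohort: pd.DataFrame
    images: imaging.GMImageSet
    mask: np.ndarray
    features: imaging.FeatureMatrix
    kernel: np.ndarray                # raw linear kernel
    kernel_residual: np.ndarray       # confound-removed kernel (full sample)
    truth: synthetic.SyntheticTruth | None = None


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def load_inputs(config: RunConfig) -> PipelineData:
    if config.cohort_path is not None:
        cohort = synthetic.read_cohort_table(config.cohort_path)
        images = imaging.read_images(config.image_paths)
        truth = None
    else:
        cohort, images, truth = synthetic.generate_cohort(config.synthetic)
    mask = imaging.build_mask(images, config.mask_threshold, config.mask_rule)
    features = imaging.vectorize(images, mask)
    K = kernels.linear_kernel(features)
    C = kernels.confound_design(cohort, config.confound_columns)
    K_res = kernels.remove_confounds(K, C)
    return PipelineData(cohort=cohort, images=images, mask=mask,
                        features=features, kernel=K, kernel_residual=K_res,
                        truth=truth)


def _pair_indices(cohort: pd.DataFrame, pairs) -> list[tuple[int, int]]:
    pos = {sid: i for i, sid in enumerate(cohort["subject_id"])}
    return [(pos[a], pos[b]) for a, b in pairs]


def run_classify_pairs(data: PipelineData, config: RunConfig) -> dict:
    """Three binary risk-group classifications on gender/age-matched pairs,
    each with leave-pair-out CV, permutation p for accuracy, and the
    projection-score correlation (all subjects and correctly classified)."""
    add_one = config.p_correction == "add-one"
    out = {}
    for hi, lo in PAIRED_COMPARISONS:
        match = clinical.match_groups(data.cohort, hi, lo, config.age_caliper)
        if not match.pairs:
            out[f"{hi}_vs_{lo}"] = {"skipped": "no feasible matched pairs"}
            continue
        idx_pairs = _pair_indices(data.cohort, match.pairs)
        subjects = sorted({i for p in idx_pairs for i in p})
        labels = np.zeros(len(data.cohort), dtype=int)
        for a, b in idx_pairs:
            labels[a], labels[b] = 1, -1   # first group of the pair is higher risk
        result = classify.leave_pair_out_cv(
            data.kernel_residual, labels, idx_pairs, C_param=config.svm_c,
            subject_ids=list(data.cohort["subject_id"]))

        sub_labels = labels[subjects]

        def accuracy_stat(perm_labels, _subjects=subjects, _pairs=idx_pairs):
            full = np.zeros(len(data.cohort), dtype=int)
            full[_subjects] = perm_labels
            return classify.leave_pair_out_cv(
                data.kernel_residual, full, _pairs, C_param=config.svm_c).accuracy

        perm = permutation_test(accuracy_stat, sub_labels, B=config.B,
                                tail="greater", seed=config.seed,
                                add_one=add_one)
        fchdr = data.cohort["fchdr"].to_numpy(dtype=float)
        out[f"{hi}_vs_{lo}"] = {
            "n_pairs": len(idx_pairs),
            "n_subjects": 2 * len(idx_pairs),
            **classify.metrics_percent(result.accuracy, result.sensitivity,
                                       result.specificity),
            "p_accuracy": perm.p_value, "p_accuracy_label": perm.p_label,
            "projection_r_all": classify.projection_correlation(result, fchdr, "all"),
            "projection_r_correct": classify.projection_correlation(result, fchdr, "correct"),
        }
    return out


def run_regress_fchdr(data: PipelineData, config: RunConfig,
                      subgroup: str = "all") -> dict:
    """Leave-one-out SVR of the FCHDR score with permutation p-values."""
    battery = regress.run_factor_battery(
        data.cohort, data.kernel, factors=["fchdr"], subgroup=subgroup,
        confound_columns=config.confound_columns, C_param=config.svr_c,
        epsilon=config.svr_epsilon, B=config.B, seed=config.seed)
    return battery.iloc[0].to_dict()


def run_factor_batteries(data: PipelineData, config: RunConfig,
                         subgroups=("all",),
                         factors=regress.FACTORS) -> pd.DataFrame:
    tables = [
        regress.run_factor_battery(
            data.cohort, data.kernel, factors=factors, subgroup=sg,
            confound_columns=config.confound_columns, C_param=config.svr_c,
            epsilon=config.svr_epsilon, B=config.B, seed=config.seed)
        for sg in subgroups]
    return pd.concat(tables, ignore_index=True)


def run_diabetes_classification(data: PipelineData, config: RunConfig) -> dict:
    """Dichotomous diabetic vs non-diabetic leave-one-out classification."""
    flags = np.array([
        clinical.diabetes_status(g, bool(m))
        for g, m in zip(data.cohort["glucose"], data.cohort["hypoglycemic_meds"])])
    if flags.all() or not flags.any():
        return {"skipped": "single diabetes class in cohort"}
    result = regress.classify_dichotomous_factor(
        data.kernel_residual, flags, C_param=config.svm_c)
    labels = np.where(flags, 1, -1)

    def acc_stat(perm_labels):
        return regress.classify_dichotomous_factor(
            data.kernel_residual, perm_labels == 1, C_param=config.svm_c).accuracy

    perm = permutation_test(acc_stat, labels, B=config.B, tail="greater",
                            seed=config.seed,
                            add_one=config.p_correction == "add-one")
    n_pos = int(flags.sum())
    return {"n": len(flags), "n_diabetic": n_pos,
            "majority_rate": max(n_pos, len(flags) - n_pos) / len(flags),
            "accuracy": result.accuracy, "p_accuracy": perm.p_value}


def run_weight_map(data: PipelineData, config: RunConfig, out_dir: Path) -> dict:
    """Fit SVR on the full confound-removed kernel and export the primal
    voxel weight map (raw and unit-norm) with sidecar metadata."""
    from sklearn.svm import SVR

    y, _, _ = regress.znormalize(data.cohort["fchdr"].to_numpy(dtype=float))
    svr = SVR(kernel="precomputed", C=config.svr_c, epsilon=config.svr_epsilon)
    svr.fit(data.kernel_residual, y)
    C = kernels.confound_design(data.cohort, config.confound_columns)
    R = kernels.residual_matrix(C)
    wmap = weights.compute_weights(svr, data.features, R=R,
                                   affine=data.images.affine)
    meta = {"model": "SVR", "target": "fchdr",
            "C": config.svr_c, "epsilon": config.svr_epsilon,
            "confounds": list(config.confound_columns)}
    raw_path = weights.write_weight_map(wmap, out_dir / "weight_map_fchdr.nii", meta)
    unit_path = weights.write_weight_map(
        wmap.unit_norm(), out_dir / "weight_map_fchdr_unitnorm.nii", meta)
    return {"raw": str(raw_path), "unit_norm": str(unit_path),
            "n_voxels": int(data.mask.sum())}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected analyses; returns the result bundle (also
    written under config.out_dir)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    echo = asdict(config)
    _write_json(echo, out_dir / "config_echo.json")

    data = load_inputs(config)
    synthetic.write_cohort_table(data.cohort, out_dir / "cohort.tsv")
    imaging.write_mask(data.mask, data.images.affine, out_dir / "mask.nii")

    bundle: dict = {"config": echo, "n_subjects": len(data.cohort),
                    "n_masked_voxels": int(data.mask.sum())}
    stage = None
    try:
        if "classify-pairs" in config.analyses:
            stage = "classify-pairs"
            bundle["classification"] = run_classify_pairs(data, config)
        if "regress-fchdr" in config.analyses:
            stage = "regress-fchdr"
            bundle["regression_fchdr"] = run_regress_fchdr(data, config)
        if "regress-factors" in config.analyses:
            stage = "regress-factors"
            table = run_factor_batteries(data, config, subgroups=("all",))
            table.to_csv(out_dir / "factor_battery.tsv", sep="\t", index=False)
            bundle["factor_battery"] = table.to_dict("records")
        if "regress-by-gender" in config.analyses:
            stage = "regress-by-gender"
            table = run_factor_batteries(data, config, subgroups=("female", "male"))
            table.to_csv(out_dir / "factor_battery_by_gender.tsv", sep="\t", index=False)
            bundle["factor_battery_by_gender"] = table.to_dict("records")
        if "regress-apoe-split" in config.analyses:
            stage = "regress-apoe-split"
            table = run_factor_batteries(
                data, config, subgroups=("apoe4_carriers", "matched_noncarriers"),
                factors=["fchdr"])
            table.to_csv(out_dir / "apoe_split.tsv", sep="\t", index=False)
            bundle["apoe_split"] = table.to_dict("records")
        if "diabetes-classify" in config.analyses:
            stage = "diabetes-classify"
            bundle["diabetes"] = run_diabetes_classification(data, config)
        if "weights" in config.analyses:
            stage = "weights"
            bundle["weight_maps"] = run_weight_map(data, config, out_dir)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    bundle["run_log"] = {"version": __version__, "seed": config.seed,
                         "elapsed_s": round(time.time() - t0, 3)}
    _write_json(bundle, out_dir / "results.json")
    return bundle
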