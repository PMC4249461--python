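"""Back-projection of kernel SVM/SVR solutions to voxel weight maps.

For a linear kernel the primal weight vector is recovered from the dual as
``w = (R X)' a`` where ``a`` holds the dual coefficients (alpha_i y_i for
classification, alpha_i - alpha_i* for regression) and ``R`` is the
residual-forming confound projector the kernel was trained under; the
weights therefore live in the residualized feature space.  Decision values
computed from (w, b) on residualized features reproduce the kernel
machine's decision values exactly.

The map is one global multivariate pattern: every voxel contributes
jointly, so it is not appropriate to make regional inferences from single
voxels.  The sign convention is positive = higher gray matter associated
with a higher predicted score/class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .imaging import unmask

__all__ = ["WeightMap", "compute_weights", "write_weight_map", "read_weight_map"]


@dataclass
class WeightMap:
    weights: np.ndarray          # one weight per masked voxel
    mask: np.ndarray             # boolean 3-D grid
    affine: np.ndarray
    bias: float = 0.0
    normalization: str = "raw"   # {"raw", "unit-norm"}

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != int(self.mask.sum()):
            raise ValueError(
                f"{self.weights.size} weights for {int(self.mask.sum())} masked voxels")

    def to_grid(self) -> np.ndarray:
        """Render onto the 3-D grid; zero outside the mask."""
        return unmask(self.weights, self.mask)

    def unit_norm(self) -> "WeightMap":
        norm = np.linalg.norm(self.weights)
        if norm == 0:
            raise ValueError("zero weight vector cannot be normalized")
        return WeightMap(weights=self.weights / norm, mask=self.mask,
                         affine=self.affine, bias=self.bias,
                         normalization="unit-norm")


def _full_dual_vector(model, n_train: int) -> np.ndarray:
    """Expand support-vector dual coefficients to one entry per training
    subject (zeros off-support).  Accepts the package's SVMModel or a fitted
    scikit-learn SVR/SVC with a precomputed kernel."""
    a = np.zeros(n_train)
    if hasattr(model, "dual_coef") and hasattr(model, "support"):
        a[model.support] = model.dual_coef
    elif hasattr(model, "dual_coef_"):
        a[model.support_] = model.dual_coef_.ravel()
    else:
        raise TypeError(f"cannot extract dual coefficients from {type(model)!r}")
    return a


def compute_weights(model, X, R: np.ndarray | None = None,
                    mask: np.ndarray | None = None,
                    affine: np.ndarray | None = None) -> WeightMap:
    """Recover the primal voxel weight vector from a dual solution.

    ``X`` is the raw feature matrix the kernel was built from (n x voxels,
    or a FeatureMatrix); ``R`` the residual projector used for confound
    removal (identity if None).  The model must have been trained on the
    kernel of R.X (i.e. on R K R).
    """
    mask_ = mask if mask is not None else getattr(X, "mask", None)
    values = np.asarray(getattr(X, "values", X), dtype=float)
    n = values.shape[0]
    a = _full_dual_vector(model, n)
    Xr = values if R is None else np.asarray(R, dtype=float) @ values
    w = Xr.T @ a
    bias = float(getattr(model, "bias", 0.0)
                 if hasattr(model, "bias") else model.intercept_[0])
    if mask_ is None:
        mask_ = np.ones((w.size, 1, 1), dtype=bool)  # degenerate 1-D layout
    return WeightMap(weights=w, mask=np.asarray(mask_, dtype=bool),
                     affine=affine if affine is not None else np.eye(4),
                     bias=bias)


def write_weight_map(wmap: WeightMap, path, metadata: dict | None = None) -> Path:
    """Write the map as NIfTI plus a JSON sidecar with model context.

    The sidecar records the normalization and the single-voxel caveat so
    downstream consumers carry it along.
    """
    path = Path(path)
    nib.save(nib.Nifti1Image(wmap.to_grid(), wmap.affine), str(path))
    sidecar = {
        "normalization": wmap.normalization,
        "bias": wmap.bias,
        "n_voxels": int(wmap.mask.sum()),
        "sign_convention": "positive = higher GM with higher predicted score",
        "caveat": ("weights form one global multivariate pattern; "
                   "no regional inference from single voxels"),
    }
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_weight_map(path, mask: np.ndarray) -> WeightMap:
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    meta_path = Path(path).with_suffix(".json")
    norm = "raw"
    if meta_path.exists():
        norm = json.loads(meta_path.read_text()).get("normalization", "raw")
    return WeightMap(weights=grid[mask], mask=mask, affine=img.affine,
                     normalization=norm)
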