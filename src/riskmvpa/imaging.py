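"""Gray-matter image I/O, analysis mask, and subject x voxel feature matrix.

Images are 3-D gray-matter probability maps (each voxel value in [0, 1] is
the probability that the voxel contains gray matter), assumed already
segmented, spatially normalized and smoothed upstream.  The analysis mask
discards voxels with less than 15% probability of containing gray matter;
voxels exactly at threshold are retained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["GMImageSet", "FeatureMatrix", "read_images", "write_images",
           "build_mask", "vectorize", "unmask"]

DEFAULT_GM_THRESHOLD = 0.15


class ImageFormatError(ValueError):
    """Inconsistent image geometry across subjects."""


class DegenerateInputError(ValueError):
    """An operation produced an empty or unusable result (e.g. empty mask)."""


@dataclass
class GMImageSet:
    """Stack of co-registered gray-matter probability maps.

    ``data`` is subject x X x Y x Z; all subjects share shape and affine.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_ids: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ImageFormatError(f"expected 4-D stack, got shape {self.data.shape}")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ImageFormatError("subject_ids length does not match stack")
        lo, hi = self.data.min(), self.data.max()
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ImageFormatError(
                f"gray-matter probabilities must lie in [0, 1]; got range [{lo}, {hi}]")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class FeatureMatrix:
    """Masked subject x voxel matrix with the mask and voxel coordinates."""

    values: np.ndarray        # n_subjects x n_masked_voxels
    mask: np.ndarray          # boolean 3-D grid
    voxel_index: np.ndarray   # n_masked_voxels x 3 integer coordinates

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def read_images(paths) -> GMImageSet:
    """Load per-subject 3-D NIfTI files (or one 4-D file) into a stack.

    Subject order follows the input order.  All files must agree on shape
    and affine; a mismatch is reported with the offending file name.
    """
    if isinstance(paths, (str, os.PathLike)):
        img = nib.load(str(paths))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[None]
        else:
            data = np.moveaxis(data, -1, 0)
        ids = [f"{Path(paths).name}:{i}" for i in range(data.shape[0])]
        return GMImageSet(data=data, affine=img.affine, subject_ids=ids)

    vols, affine, shape = [], None, None
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 3:
            raise ImageFormatError(f"{p}: expected a 3-D volume, got shape {arr.shape}")
        if shape is None:
            shape, affine = arr.shape, img.affine
        elif arr.shape != shape:
            raise ImageFormatError(f"{p}: shape {arr.shape} != expected {shape}")
        elif not np.allclose(img.affine, affine):
            raise ImageFormatError(f"{p}: affine differs from first image")
        vols.append(arr)
    return GMImageSet(data=np.stack(vols), affine=affine,
                      subject_ids=[Path(p).stem for p in paths])


def write_images(images: GMImageSet, directory, stem: str = "gm") -> list[Path]:
    """Write one 3-D NIfTI per subject; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, sid in enumerate(images.subject_ids):
        path = directory / f"{stem}_{sid}.nii"
        nib.save(nib.Nifti1Image(images.data[i], images.affine), str(path))
        out.append(path)
    return out


def build_mask(images: GMImageSet, threshold: float = DEFAULT_GM_THRESHOLD,
               rule: str = "mean") -> np.ndarray:
    """Common analysis mask at a gray-matter probability threshold.

    rule="mean" keeps voxels whose across-subject mean is >= threshold
    (default); rule="all" keeps voxels >= threshold in every subject.
    Voxels exactly at threshold are kept: only values strictly below it
    are discarded.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if rule == "mean":
        mask = images.data.mean(axis=0) >= threshold
    elif rule == "all":
        mask = (images.data >= threshold).all(axis=0)
    else:
        raise ValueError(f"unknown mask rule {rule!r}; expected 'mean' or 'all'")
    if not mask.any():
        raise DegenerateInputError("mask is empty at this threshold")
    return mask


def vectorize(images: GMImageSet, mask: np.ndarray) -> FeatureMatrix:
    """Flatten masked voxels to a subject x voxel matrix.

    Column order is lexicographic in (x, y, z), i.e. C-order of the grid.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != images.grid_shape:
        raise ValueError(f"mask shape {mask.shape} != image grid {images.grid_shape}")
    values = images.data[:, mask]
    voxel_index = np.argwhere(mask)
    return FeatureMatrix(values=values, mask=mask, voxel_index=voxel_index)


def unmask(row: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Place a masked voxel vector back onto the 3-D grid (zeros elsewhere)."""
    mask = np.asarray(mask, dtype=bool)
    grid = np.zeros(mask.shape, dtype=float)
    grid[mask] = row
    return grid


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))
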