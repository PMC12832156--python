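"""NIfTI input/output for CT volumes and segmentation label masks.

World coordinates are fixed to the RAS+ convention (+x right, +y anterior,
+z superior), so "posterior" always means the -y direction.  Files whose
affine encodes a different orientation are reoriented on load.  Voxel
indices are 0-based and the affine maps a voxel's *center* to world
millimetres, the standard NIfTI reading.

Attenuation values are stored as floating-point Hounsfield units after the
NIfTI ``scl_slope``/``scl_inter`` scaling has been applied; no further
calibration is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "LabelMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_same_grid",
]

_MIN_DET = 1e-12


def _validate_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < _MIN_DET:
        raise ValueError("degenerate affine: upper-left 3x3 block is singular")
    return affine


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield-unit values with a voxel-to-world affine.

    Attributes
    ----------
    voxels
        3-D float array of attenuation values (HU).
    affine
        4x4 transform taking homogeneous voxel indices ``(i, j, k, 1)`` to
        world coordinates in millimetres.
    """

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.voxels.ndim}-D")
        self.affine = _validate_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> np.ndarray:
        """Per-axis voxel spacing: column norms of the affine's 3x3 block."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_uL(self) -> float:
        """Volume of one voxel in mm^3 (identically microlitres)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class LabelMask:
    """Integer segmentation on the same grid as a :class:`CTVolume`.

    ``target_label`` identifies the structure of interest (here the third
    ventricle) within the label image.
    """

    labels: np.ndarray
    affine: np.ndarray
    target_label: int = 1

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected 3-D label image, got {labels.ndim}-D")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded, atol=1e-6):
                raise ValueError("label image contains non-integer values")
            labels = rounded.astype(np.int32)
        self.labels = labels
        self.affine = _validate_affine(self.affine)
        self.target_label = int(self.target_label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


def _load_canonical(path: os.PathLike | str) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file, reorient to RAS+, return (data, affine)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {img.ndim}-D in {path}")
    _validate_affine(img.affine)
    img = nib.as_closest_canonical(img)
    # get_fdata applies scl_slope / scl_inter
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine, dtype=float)


def read_volume(path: os.PathLike | str) -> CTVolume:
    """Read a CT volume from a NIfTI-1 file, reoriented to RAS+.

    The affine is taken from the file header (sform/qform per NIfTI
    precedence, as resolved by nibabel); values are assumed already
    HU-calibrated.
    """
    data, affine = _load_canonical(path)
    return CTVolume(voxels=data, affine=affine)


def write_volume(vol: CTVolume, path: os.PathLike | str) -> None:
    """Write a CT volume as NIfTI-1, lossless for HU grids (float64)."""
    img = nib.Nifti1Image(vol.voxels.astype(np.float64), vol.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_mask(path: os.PathLike | str, target_label: int = 1) -> LabelMask:
    """Read an integer label mask from NIfTI, reoriented to RAS+."""
    data, affine = _load_canonical(path)
    return LabelMask(labels=np.rint(data).astype(np.int32), affine=affine,
                     target_label=target_label)


def write_mask(mask: LabelMask, path: os.PathLike | str) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int32), mask.affine)
    img.header.set_data_dtype(np.int32)
    nib.save(img, str(path))


def check_same_grid(vol: CTVolume, mask: LabelMask, atol: float = 1e-4) -> None:
    """Raise ``ValueError`` unless volume and mask share shape and affine."""
    if vol.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: volume shape {vol.shape} vs mask shape {mask.shape}"
        )
    if not np.allclose(vol.affine, mask.affine, atol=atol, rtol=0):
        raise ValueError("affine mismatch between volume and mask (>1e-4)")
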