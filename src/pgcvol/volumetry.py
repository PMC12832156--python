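"""Landmark-anchored spherical-ROI calcification volumetry on head CT.

The measurement pipeline:

1. binary center of mass of the third-ventricle label in world mm;
2. ROI center placed a fixed offset posterior to it (RAS+: posterior = -y);
3. spherical ROI of fixed radius, a voxel belongs to the sphere iff its
   *center* lies within ``radius_mm`` of the ROI center;
4. ROI voxels whose attenuation strictly exceeds the HU threshold are
   counted as calcified, and their count times the voxel volume (mm^3,
   identically microlitres) is the calcification volume.

Defaults follow common practice for pineal-gland calcification: a 12 mm
radius sphere centered 20 mm posterior to the third-ventricle centroid,
thresholded at > 50 HU.  The sphere is clipped silently at the grid
boundary; ``n_roi_voxels`` makes the clipping auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import CTVolume, LabelMask, check_same_grid

__all__ = [
    "ROISpec",
    "PGCResult",
    "voxel_centers",
    "center_of_mass",
    "pineal_roi_center",
    "sphere_mask",
    "measure_pgc",
]


@dataclass(frozen=True)
class ROISpec:
    """Geometry and threshold of the pineal region of interest.

    Attributes
    ----------
    radius_mm
        Sphere radius in millimetres (default 12).
    posterior_offset_mm
        Distance from the third-ventricle centroid to the ROI center,
        along the posterior (-y) direction (default 20).
    hu_threshold
        Attenuation cutoff; voxels with HU strictly greater than this are
        counted as calcified (default 50).
    """

    radius_mm: float = 12.0
    posterior_offset_mm: float = 20.0
    hu_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.posterior_offset_mm < 0:
            raise ValueError("posterior_offset_mm must be >= 0")


@dataclass
class PGCResult:
    """Audit record of one calcification measurement."""

    ventricle_centroid_mm: np.ndarray
    roi_center_mm: np.ndarray
    n_roi_voxels: int
    n_calcified_voxels: int
    voxel_volume_uL: float
    volume_uL: float

    def to_row(self) -> dict:
        """Flatten to a dict suitable for one CSV row."""
        cx, cy, cz = self.ventricle_centroid_mm
        rx, ry, rz = self.roi_center_mm
        return {
            "centroid_x_mm": cx, "centroid_y_mm": cy, "centroid_z_mm": cz,
            "roi_x_mm": rx, "roi_y_mm": ry, "roi_z_mm": rz,
            "n_roi_voxels": self.n_roi_voxels,
            "n_calcified_voxels": self.n_calcified_voxels,
            "voxel_volume_uL": self.voxel_volume_uL,
            "volume_uL": self.volume_uL,
        }


def voxel_centers(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World coordinates of every voxel center, shape ``(3, nx, ny, nz)``."""
    affine = np.asarray(affine, dtype=float)
    idx = np.indices(shape, dtype=float)
    world = np.einsum("ab,b...->a...", affine[:3, :3], idx)
    return world + affine[:3, 3][:, None, None, None]


def center_of_mass(mask: LabelMask) -> np.ndarray:
    """Unweighted (binary) center of mass of the target label, in world mm.

    Every voxel carrying ``mask.target_label`` contributes its world-space
    center with equal weight; attenuation plays no role.
    """
    idx = np.argwhere(mask.labels == mask.target_label)
    if idx.size == 0:
        raise ValueError(
            f"label {mask.target_label} not present in mask; cannot compute centroid"
        )
    world = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    return world.mean(axis=0)


def pineal_roi_center(centroid_mm: np.ndarray, spec: ROISpec = ROISpec()) -> np.ndarray:
    """Translate the ventricle centroid posteriorly (RAS+: -y) by the offset."""
    centroid_mm = np.asarray(centroid_mm, dtype=float)
    return centroid_mm + np.array([0.0, -spec.posterior_offset_mm, 0.0])


def sphere_mask(vol: CTVolume, center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    """Boolean grid: True where the voxel-center distance to ``center_mm``
    is <= ``radius_mm``.  A sphere extending beyond the grid is clipped
    silently; the mask covers only in-grid voxels.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    center_mm = np.asarray(center_mm, dtype=float)
    world = voxel_centers(vol.shape, vol.affine)
    d2 = ((world - center_mm[:, None, None, None]) ** 2).sum(axis=0)
    return d2 <= radius_mm ** 2


def measure_pgc(vol: CTVolume, mask: LabelMask, spec: ROISpec = ROISpec()) -> PGCResult:
    """Measure calcified volume inside the pineal ROI of one scan.

    Composes centroid -> ROI center -> sphere mask -> strict HU threshold
    -> volume; all intermediates are reported in the result for audit.

    Raises
    ------
    ValueError
        If volume and mask grids disagree or the ventricle label is empty.
    """
    check_same_grid(vol, mask)
    centroid = center_of_mass(mask)
    roi_center = pineal_roi_center(centroid, spec)
    roi = sphere_mask(vol, roi_center, spec.radius_mm)
    calcified = roi & (vol.voxels > spec.hu_threshold)
    n_roi = int(roi.sum())
    n_calc = int(calcified.sum())
    return PGCResult(
        ventricle_centroid_mm=centroid,
        roi_center_mm=roi_center,
        n_roi_voxels=n_roi,
        n_calcified_voxels=n_calc,
        voxel_volume_uL=vol.voxel_volume_uL,
        volume_uL=n_calc * vol.voxel_volume_uL,
    )
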