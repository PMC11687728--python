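"""Voxel-grid containers for CT volumes and lesion segmentations.

Arrays are indexed ``[z, y, x]`` (axis 0 = axial slice direction) and carry
physical voxel spacing in millimetres aligned to the array axes, i.e.
``spacing = (dz, dy, dx)``.  NIfTI files store data in ``(x, y, z)`` order,
so the I/O helpers transpose on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

#: fixed month <-> day conversion used throughout the package
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D CT image in Hounsfield units with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Attenuation values in HU.
    spacing : tuple of float
        Voxel spacing (dz, dy, dx) in mm; all components > 0.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError("volume must be 3D")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class LesionMask:
    """Binary segmentation aligned to a :class:`VoxelVolume` grid."""

    membership: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        membership = np.asarray(self.membership).astype(bool)
        object.__setattr__(self, "membership", membership)
        if membership.ndim != 3:
            raise ValueError("mask must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def check_aligned(self, volume: VoxelVolume) -> None:
        if self.membership.shape != volume.values.shape:
            raise ValueError(
                f"mask shape {self.membership.shape} does not match "
                f"volume shape {volume.values.shape}"
            )


def save_nifti(path: str | Path, volume: VoxelVolume | LesionMask) -> None:
    """Write a volume or mask as NIfTI (data transposed to x, y, z order)."""
    if isinstance(volume, VoxelVolume):
        data = volume.values.astype(np.float32)
    else:
        data = volume.membership.astype(np.uint8)
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> VoxelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float).transpose(2, 1, 0)
    dx, dy, dz = img.header.get_zooms()[:3]
    return VoxelVolume(values=data, spacing=(float(dz), float(dy), float(dx)))


def load_mask(path: str | Path) -> LesionMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0) > 0
    dx, dy, dz = img.header.get_zooms()[:3]
    return LesionMask(membership=data, spacing=(float(dz), float(dy), float(dx)))
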