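"""3-D scalar volumes with physical voxel spacing, plus NIfTI-1 I/O.

Arrays are indexed ``(z, y, x)``; spacing is ``(dz, dy, dx)`` in cm.
NIfTI files store data in ``(x, y, z)`` order with spacing in mm, so both
directions of the round trip transpose and rescale accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume", "read_nifti", "write_nifti"]


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar voxel values (activity, intensity, or a binary mask).
    spacing : tuple of float
        Voxel edge lengths ``(dz, dy, dx)`` in cm; all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.50, 0.41, 0.41)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.data.dtype.kind == "f" and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of a single voxel in cm^3."""
        return float(np.prod(self.spacing))

    def like(self, data: np.ndarray) -> "VoxelVolume":
        """A new volume on the same grid carrying ``data``."""
        return VoxelVolume(data, self.spacing)


def write_nifti(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), spacing in the header (mm)."""
    data_xyz = np.asarray(vol.data).transpose(2, 1, 0)
    dz, dy, dx = vol.spacing
    affine = np.diag([dx * 10.0, dy * 10.0, dz * 10.0, 1.0])
    img = nib.Nifti1Image(data_xyz.astype(np.float32), affine)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> VoxelVolume:
    """Read a NIfTI volume into ``(z, y, x)`` order with spacing in cm."""
    img = nib.load(str(path))
    data_xyz = np.asanyarray(img.dataobj)
    if data_xyz.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI image, got shape {data_xyz.shape}")
    dx, dy, dz = img.header.get_zooms()[:3]
    return VoxelVolume(np.ascontiguousarray(data_xyz.transpose(2, 1, 0)),
                       (float(dz) / 10.0, float(dy) / 10.0, float(dx) / 10.0))
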