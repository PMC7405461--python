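"""Core 3D volume container and NIfTI-1 I/O.

A :class:`Volume` is the universal currency of the pipeline: a 3D non-negative
magnitude image together with its voxel spacing in millimetres.  Axis order is
(x, y, z) = (frequency encode, phase encode, slice encode); world coordinates
of voxel (i, j, k) are (i*sx, j*sy, k*sz) in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume", "load_nifti", "save_nifti"]


@dataclass
class Volume:
    """3D magnitude image with voxel spacing.

    Parameters
    ----------
    data:
        3D array of finite, non-negative intensities.
    spacing:
        Voxel edge lengths in mm, one per axis.
    normalized:
        Whether ``data`` has been min-max scaled into [0, 1].
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.data.size and self.data.min() < 0:
            raise ValueError("magnitude volume must be non-negative")
        if self.normalized and self.data.size and self.data.max() > 1 + 1e-9:
            raise ValueError("volume flagged normalized but has values > 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def fov(self) -> tuple[float, float, float]:
        """Field of view per axis in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, *, normalized: bool | None = None) -> "Volume":
        """Copy of this volume with new voxel data (same spacing)."""
        return Volume(
            data=data,
            spacing=self.spacing,
            normalized=self.normalized if normalized is None else normalized,
        )

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


def load_nifti(path) -> Volume:
    """Read a NIfTI-1 volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    data = np.abs(data)  # magnitude contract
    vmax = data.max() if data.size else 0.0
    return Volume(data=data, spacing=tuple(float(z) for z in zooms), normalized=bool(vmax <= 1 + 1e-9))


def save_nifti(vol: Volume, path, *, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 with spacing encoded in the affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
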