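"""Grid-aligned 3-D volumes with world geometry, plus NIfTI-1 I/O.

Two thin containers are used throughout the package: :class:`LabelVolume`
for integer parcellations and :class:`ScalarVolume` for PET images, modeled
PET, and masks stored as floats.  Both carry a 4x4 grid-to-world affine in
an RAS+ world convention; world coordinates are in mm and are obtained as
``affine @ [i, j, k, 1]`` with 0-based (i, j, k) indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelVolume", "ScalarVolume", "centered_affine"]


def centered_affine(shape, spacing_mm) -> np.ndarray:
    """Diagonal affine placing the world origin at the grid center.

    Centering makes rotations about the world origin act about the volume
    center, which is the convention the registration module uses.
    """
    shape = np.asarray(shape, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = -spacing * (shape - 1) / 2.0
    return aff


@dataclass
class Volume:
    """A 3-D grid with a grid-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self):
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data), self.affine), str(path))


class ScalarVolume(Volume):
    """Float-valued volume (PET activity, modeled PET, masks-as-float)."""

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data, dtype=np.float64)

    @classmethod
    def from_nifti(cls, path) -> "ScalarVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)


class LabelVolume(Volume):
    """Integer-labeled parcellation volume; background is label 0."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label data is not integral")
            self.data = rounded
        self.data = np.asarray(self.data, dtype=np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be >= 0")

    @classmethod
    def from_nifti(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), img.affine)

    def labels_present(self, include_background: bool = False) -> np.ndarray:
        ids = np.unique(self.data)
        if not include_background:
            ids = ids[ids != 0]
        return ids
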