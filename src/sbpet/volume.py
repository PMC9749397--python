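"""Lightweight 3-D volume container with voxel spacing and a grid-to-world affine.

All pipeline stages exchange :class:`Volume` objects.  The container is a thin
wrapper over a numpy array plus a NIfTI-style RAS+ affine; it deliberately does
not own any resampling logic — every operator in this package works on volumes
that already share one grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3-D scalar grid with world-coordinate metadata.

    Parameters
    ----------
    data:
        3-D numpy array (any dtype; images are float, masks 0/1).
    affine:
        4x4 grid-to-world affine (RAS+ convention, mm). Defaults to identity,
        i.e. a 1 mm isotropic grid at the world origin.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume sharing this volume's grid metadata."""
        return replace(self, data=np.asarray(data))

    def same_grid(self, other: "Volume", tol_mm: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol_mm
        )

    # -- NIfTI round trip ---------------------------------------------------

    def to_nifti(self, dtype=np.float32) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=dtype), self.affine)
        img.header.set_zooms(tuple(self.spacing))
        return img

    def save(self, path, dtype=np.float32) -> None:
        nib.save(self.to_nifti(dtype=dtype), str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), np.asarray(img.affine))

    @classmethod
    def like(cls, other: "Volume", data: np.ndarray) -> "Volume":
        return cls(np.asarray(data), other.affine.copy())
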