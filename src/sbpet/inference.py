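"""Whole-volume synthesis: sagittal patch tiling and weighted overlap fusion.

The model predicts patches of ``w`` neighboring full sagittal slices.  At
inference every stride-1 patch position is evaluated and the overlapping
predictions are fused with a weighted average whose weight decreases with
the sagittal distance of a slice to the center of its originating patch
(triangular profile by default), so slices predicted near a patch border
contribute less than the same slices predicted mid-patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = [
    "PatchGrid",
    "patch_positions",
    "fusion_weight_profile",
    "extract_patches",
    "fuse_patches",
    "synthesize_volume",
]


def patch_positions(s: int, w: int, drop_last: bool = False) -> list[int]:
    """Stride-1 start indices covering every sagittal slice.

    ``s - w + 1`` positions (0 .. s-w inclusive).  ``drop_last`` reproduces
    an ``s - w`` count convention that leaves the final start out; slice
    coverage of the remaining positions is still complete for w >= 2.
    """
    if not 1 <= w <= s:
        raise ValueError(f"patch width {w} must satisfy 1 <= w <= {s}")
    pos = list(range(s - w + 1))
    if drop_last and len(pos) > 1:
        pos = pos[:-1]
    return pos


def fusion_weight_profile(w: int, shape: str = "triangular") -> np.ndarray:
    """Per-offset fusion weights of length ``w``.

    Triangular (default): weight(o) = (w/2 + 0.5) - |o - (w-1)/2| — strictly
    positive, symmetric, maximal at the center, linear decay to 1 at the
    patch edges.  'gaussian' and 'uniform' are available alternatives.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    offsets = np.arange(w, dtype=float)
    center = (w - 1) / 2.0
    if shape == "triangular":
        prof = (w / 2.0 + 0.5) - np.abs(offsets - center)
    elif shape == "gaussian":
        sigma = max(w / 4.0, 0.5)
        prof = np.exp(-0.5 * ((offsets - center) / sigma) ** 2)
    elif shape == "uniform":
        prof = np.ones(w)
    else:
        raise ValueError(f"unknown weight profile shape: {shape!r}")
    assert (prof > 0).all()
    return prof


@dataclass(frozen=True)
class PatchGrid:
    """Tiling plan along the sagittal axis."""

    n_slices: int
    patch_width: int
    positions: tuple[int, ...]
    weight_profile: np.ndarray

    @classmethod
    def plan(cls, n_slices: int, patch_width: int, weight_shape: str = "triangular",
             drop_last: bool = False) -> "PatchGrid":
        return cls(
            n_slices=n_slices,
            patch_width=patch_width,
            positions=tuple(patch_positions(n_slices, patch_width, drop_last)),
            weight_profile=fusion_weight_profile(patch_width, weight_shape),
        )


def extract_patches(data: np.ndarray, positions, w: int) -> list[np.ndarray]:
    """Slice (w, H, W) patches out of a volume array along axis 0."""
    return [data[p : p + w] for p in positions]


def fuse_patches(patches, positions, profile: np.ndarray, s: int) -> np.ndarray:
    """Distance-weighted average of overlapping sagittal patches.

    output(x) = sum_p weight_p(x) patch_p(x) / sum_p weight_p(x); raises if
    any slice is covered by no patch.
    """
    patches = [np.asarray(p, dtype=float) for p in patches]
    if len(patches) != len(positions):
        raise ValueError("one patch per position required")
    w = len(profile)
    accum = np.zeros((s,) + patches[0].shape[1:])
    weight = np.zeros(s)
    for patch, pos in zip(patches, positions):
        if patch.shape[0] != w:
            raise ValueError("patch width inconsistent with weight profile")
        accum[pos : pos + w] += profile[:, None, None] * patch
        weight[pos : pos + w] += profile
    if (weight == 0).any():
        uncovered = np.flatnonzero(weight == 0)
        raise ValueError(f"slices not covered by any patch: {uncovered.tolist()}")
    return accum / weight[:, None, None]


def synthesize_volume(
    mri_z: Volume,
    mask: Volume,
    model,
    *,
    weight_shape: str = "triangular",
    drop_last: bool = False,
) -> Volume:
    """Synthesize a full baseline PET (sbPET) volume from a z-scored MRI.

    All sagittal patches are run through the model (sketcher then refiner via
    ``model.predict_patch``), fused with the weighted-average scheme, clamped
    to non-negative uptake, and zeroed outside the brain mask.
    """
    w = model.arch.patch_shape[0] if hasattr(model, "arch") else getattr(model, "patch_width")
    s = mri_z.shape[0]
    if mri_z.shape[1:] != mask.shape[1:] or mri_z.shape != mask.shape:
        raise ValueError("MRI and mask grids differ")
    grid = PatchGrid.plan(s, w, weight_shape, drop_last)
    preds = [model.predict_patch(p) for p in extract_patches(np.asarray(mri_z.data), grid.positions, w)]
    fused = fuse_patches(preds, grid.positions, grid.weight_profile, s)
    fused = np.clip(fused, 0.0, None)
    fused[np.asarray(mask.data) <= 0] = 0.0
    return mri_z.with_data(fused)
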