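"""Normalization and grid-standardization operators.

These operators assume volumes that are already co-registered, bias-corrected
and skull-stripped; they implement the intensity and grid conventions the
synthesis model is trained under:

* brain-mask dilation by a metric radius (default 10 mm),
* MRI z-normalization using only gray/white-matter voxels, with a fixed
  sentinel value (-7) outside the dilated mask so the network can tell
  unmasked voxels from tissue,
* PET unit normalization by the mean of the top-2% GM/WM voxels of a 3 mm
  blurred copy (the divisor is retained for later denormalization),
* centered crop/pad to a cubic grid with the affine updated so world
  coordinates of retained voxels are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import SubjectRecord
from .volume import Volume

__all__ = [
    "NormalizedSubject",
    "dilate_mask",
    "znormalize_mri",
    "normalize_pet",
    "crop_pad_to_cube",
    "gaussian_blur",
    "preprocess_subject",
    "SENTINEL",
    "FWHM_TO_SIGMA",
    "TISSUE_THRESHOLD",
]

SENTINEL = -7.0
#: FWHM -> sigma for a Gaussian: fwhm / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
#: a voxel "depicts" GM or WM when gm + wm probability exceeds this
TISSUE_THRESHOLD = 0.5


@dataclass
class NormalizedSubject:
    """A subject in model intensity space."""

    mri_z: Volume
    pet_n: Volume
    pet_norm_constant: float  # original uptake units per normalized unit
    dilated_mask: Volume
    brain_mask: Volume
    gm: Volume
    wm: Volume
    provenance: dict


def dilate_mask(mask: Volume, radius_mm: float) -> Volume:
    """Dilate a binary mask by a Euclidean metric radius.

    A voxel is in the output iff its center lies within ``radius_mm`` of some
    input mask voxel center; anisotropic spacing is honored in mm.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    m = mask.data > 0
    if not m.any():
        raise ValueError("cannot dilate an empty mask")
    if radius_mm == 0:
        return mask.with_data(m.astype(np.uint8))
    dist = ndimage.distance_transform_edt(~m, sampling=tuple(mask.spacing))
    return mask.with_data((dist <= radius_mm).astype(np.uint8))


def _tissue_mask(gm: Volume, wm: Volume, threshold: float = TISSUE_THRESHOLD) -> np.ndarray:
    return (gm.data + wm.data) > threshold


def znormalize_mri(
    mri: Volume,
    gm: Volume,
    wm: Volume,
    dilated_mask: Volume,
    sentinel: float = SENTINEL,
) -> Volume:
    """Z-score the MRI using only GM/WM voxel statistics.

    The mean and (population) SD are computed over voxels with combined GM+WM
    probability above :data:`TISSUE_THRESHOLD`; normalization is applied
    inside the dilated mask and every voxel outside it is set to ``sentinel``
    exactly.  This keeps the intensity scale stable under varying degrees of
    atrophy, which would otherwise shift whole-image statistics.
    """
    tissue = _tissue_mask(gm, wm)
    vals = mri.data[tissue]
    if vals.size < 2:
        raise ValueError("fewer than 2 GM/WM voxels; cannot z-normalize")
    mu = float(vals.mean())
    sd = float(vals.std())  # population convention
    if sd == 0:
        raise ValueError("degenerate intensity distribution (zero tissue SD)")
    out = (mri.data - mu) / sd
    out = np.where(dilated_mask.data > 0, out, sentinel)
    return mri.with_data(out)


def normalize_pet(
    pet: Volume,
    gm: Volume,
    wm: Volume,
    blur_fwhm_mm: float = 3.0,
    top_pct: float = 2.0,
) -> tuple[Volume, float]:
    """Normalize PET by the mean of its top-``top_pct``% GM/WM voxels.

    The top fraction is selected on a Gaussian-blurred copy (default 3 mm
    FWHM) — voxels whose blurred value is at or above the
    ``100 - top_pct`` linear-interpolation percentile of blurred GM/WM
    values — and the constant is the mean of those blurred values.  The
    returned volume is the *unblurred* PET divided by that constant.

    Returns ``(pet / c, c)``.
    """
    tissue = _tissue_mask(gm, wm)
    if not tissue.any():
        raise ValueError("empty GM/WM voxel set")
    blurred = gaussian_blur(pet, blur_fwhm_mm).data
    tissue_vals = blurred[tissue]
    threshold = np.percentile(tissue_vals, 100.0 - top_pct)
    selected = tissue_vals[tissue_vals >= threshold]
    c = float(selected.mean())
    if c <= 0:
        raise ValueError("PET normalization constant is non-positive")
    return pet.with_data(pet.data / c), c


def crop_pad_to_cube(vol: Volume, size: int, fill: float = 0.0) -> Volume:
    """Center-crop and/or symmetrically pad each axis to ``size``.

    When the crop/pad amount is odd, the larger share goes to the high-index
    side.  The affine origin is shifted so retained voxels keep their world
    coordinates.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    data = vol.data
    shift = np.zeros(3)  # old index of new index 0, per axis
    slices = []
    pads = []
    for ax in range(3):
        n = data.shape[ax]
        if n >= size:
            t = n - size
            lo = t // 2
            slices.append(slice(lo, lo + size))
            pads.append((0, 0))
            shift[ax] = lo
        else:
            p = size - n
            lo = p // 2
            slices.append(slice(None))
            pads.append((lo, p - lo))
            shift[ax] = -lo
    out = data[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, mode="constant", constant_values=fill)
    affine = vol.affine.copy()
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ shift
    return Volume(out, affine)


def gaussian_blur(vol: Volume, fwhm_mm: float) -> Volume:
    """Gaussian blur specified by FWHM in mm (PET convention).

    The sigma per axis is ``fwhm * FWHM_TO_SIGMA / spacing``; ``fwhm_mm = 0``
    is the identity.  Reflect boundary handling approximately preserves the
    volume mean.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.spacing
    return vol.with_data(ndimage.gaussian_filter(np.asarray(vol.data, float), sigma_vox, mode="reflect"))


def preprocess_subject(
    record: SubjectRecord,
    *,
    size: int | None = None,
    dilate_mm: float = 10.0,
    sentinel: float = SENTINEL,
    pet_top_pct: float = 2.0,
    blur_fwhm_mm: float = 3.0,
) -> NormalizedSubject:
    """Run the full normalization chain on one aligned subject."""
    dmask = dilate_mask(record.mask, dilate_mm)
    mri_z = znormalize_mri(record.mri, record.gm, record.wm, dmask, sentinel)
    pet_n, c = normalize_pet(record.pet, record.gm, record.wm, blur_fwhm_mm, pet_top_pct)

    mask = record.mask
    gm, wm = record.gm, record.wm
    if size is not None:
        mri_z = crop_pad_to_cube(mri_z, size, fill=sentinel)
        pet_n = crop_pad_to_cube(pet_n, size, fill=0.0)
        dmask = crop_pad_to_cube(dmask, size, fill=0)
        mask = crop_pad_to_cube(mask, size, fill=0)
        gm = crop_pad_to_cube(gm, size, fill=0.0)
        wm = crop_pad_to_cube(wm, size, fill=0.0)

    return NormalizedSubject(
        mri_z=mri_z,
        pet_n=pet_n,
        pet_norm_constant=c,
        dilated_mask=dmask,
        brain_mask=mask,
        gm=gm,
        wm=wm,
        provenance={
            "dilate_mm": dilate_mm,
            "sentinel": sentinel,
            "pet_top_pct": pet_top_pct,
            "blur_fwhm_mm": blur_fwhm_mm,
            "pet_norm_constant": c,
            "size": size,
        },
    )
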