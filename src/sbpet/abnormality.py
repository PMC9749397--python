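"""Personalized abnormality mapping against the synthetic baseline.

With the subject's own synthetic baseline PET (sbPET) as the healthy
reference, abnormal uptake is read out voxel-wise as the relative percent
difference

    Z%(x) = (Y(x) - Yhat(x)) / Yhat(x) * 100%

where Y is the true PET and Yhat the post-normalized sbPET.  Negative Z% is
hypometabolism (the FDG-PET signature of neurodegeneration), positive Z% is
hypermetabolism.  Before the division the sbPET is post-normalized so that
its mean over a subject-specific healthy-uptake region (top-2% GM/WM uptake
of the blurred true PET) matches the true PET, and both volumes are blurred
by 3 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import gaussian_blur
from .volume import Volume

__all__ = [
    "AbnormalityMap",
    "healthy_region_mask",
    "post_normalize_sbpet",
    "zmap",
    "abnormality_analysis",
    "regional_summary",
    "group_mean_map",
]

#: denominator guard: Yhat below eps_frac * (healthy-region mean) is undefined
EPS_FRACTION = 1e-6


@dataclass
class AbnormalityMap:
    """Z% volume (NaN where undefined) plus its normalization provenance."""

    z_pct: Volume
    post_norm_factor: float
    healthy_region: Volume

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.z_pct.data)


def healthy_region_mask(
    pet: Volume,
    gm: Volume,
    wm: Volume,
    blur_fwhm_mm: float = 3.0,
    top_pct: float = 2.0,
    tissue_threshold: float = 0.5,
) -> Volume:
    """GM/WM voxels in the top ``top_pct``% of blurred true-PET uptake.

    This is the subject's own high-uptake (presumed healthy) region used to
    bring the sbPET onto the true PET's intensity scale.  Ties at the
    percentile threshold are included.
    """
    tissue = (gm.data + wm.data) > tissue_threshold
    if not tissue.any():
        raise ValueError("empty GM/WM voxel set")
    blurred = gaussian_blur(pet, blur_fwhm_mm).data
    vals = blurred[tissue]
    threshold = np.percentile(vals, 100.0 - top_pct)
    region = tissue & (blurred >= threshold)
    if not region.any():
        raise ValueError("degenerate PET: healthy region is empty")
    return pet.with_data(region.astype(np.uint8))


def post_normalize_sbpet(
    sbpet: Volume, pet: Volume, region: Volume
) -> tuple[Volume, float]:
    """Scale the sbPET so its healthy-region mean matches the true PET's.

    Returns ``(f * sbpet, f)`` with ``f = mean(pet | region) / mean(sbpet |
    region)``.
    """
    m = region.data > 0
    if not m.any():
        raise ValueError("post-normalization region is empty")
    sb_mean = float(sbpet.data[m].mean())
    if sb_mean <= 0:
        raise ValueError("sbPET mean over the healthy region is non-positive")
    f = float(pet.data[m].mean()) / sb_mean
    return sbpet.with_data(sbpet.data * f), f


def zmap(
    pet: Volume,
    sbpet_post: Volume,
    brain_mask: Volume,
    blur_fwhm_mm: float = 3.0,
    eps: float | None = None,
    post_norm_factor: float = 1.0,
    healthy_region: Volume | None = None,
) -> AbnormalityMap:
    """Voxel-wise Z% of the true PET relative to the post-normalized sbPET.

    Both volumes are blurred (default 3 mm FWHM) before the division; Z% is
    defined only inside the brain mask and where the blurred baseline
    exceeds ``eps`` (default ``1e-6 x`` its within-brain mean); elsewhere it
    is NaN and excluded from all summaries.
    """
    if pet.shape != sbpet_post.shape or pet.shape != brain_mask.shape:
        raise ValueError("volumes must share one grid")
    y = gaussian_blur(pet, blur_fwhm_mm).data
    yhat = gaussian_blur(sbpet_post, blur_fwhm_mm).data
    brain = brain_mask.data > 0
    if eps is None:
        ref = float(yhat[brain].mean()) if brain.any() else 0.0
        eps = EPS_FRACTION * abs(ref)
    defined = brain & (yhat > eps)
    z = np.full(pet.shape, np.nan)
    z[defined] = 100.0 * (y[defined] - yhat[defined]) / yhat[defined]
    return AbnormalityMap(
        z_pct=pet.with_data(z),
        post_norm_factor=post_norm_factor,
        healthy_region=healthy_region
        if healthy_region is not None
        else pet.with_data(np.zeros(pet.shape, dtype=np.uint8)),
    )


def abnormality_analysis(
    pet: Volume,
    sbpet: Volume,
    brain_mask: Volume,
    gm: Volume,
    wm: Volume,
    blur_fwhm_mm: float = 3.0,
    top_pct: float = 2.0,
) -> AbnormalityMap:
    """Full chain: healthy region -> post-normalization -> blur -> Z%."""
    region = healthy_region_mask(pet, gm, wm, blur_fwhm_mm, top_pct)
    sb_post, f = post_normalize_sbpet(sbpet, pet, region)
    return zmap(pet, sb_post, brain_mask, blur_fwhm_mm,
                post_norm_factor=f, healthy_region=region)


def regional_summary(abn: AbnormalityMap, atlas: Volume) -> pd.DataFrame:
    """Per-region mean/SD/voxel-count of defined Z% values.

    Regions with no defined voxels are reported with NaN statistics and a
    zero count (present, not silently dropped).
    """
    if atlas.shape != abn.z_pct.shape:
        raise ValueError("atlas grid does not match the abnormality map")
    labels = np.asarray(atlas.data).astype(int)
    z = abn.z_pct.data
    rows = []
    for label in sorted(np.unique(labels[labels > 0])):
        vals = z[(labels == label) & abn.defined]
        rows.append(
            {
                "region": int(label),
                "mean_z_pct": float(vals.mean()) if vals.size else np.nan,
                "sd_z_pct": float(vals.std()) if vals.size else np.nan,
                "n_voxels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def group_mean_map(maps: list[AbnormalityMap]) -> Volume:
    """Voxel-wise group average of Z% maps on a shared grid.

    Each voxel averages only the maps in which it is defined; voxels defined
    in no map are NaN.
    """
    if not maps:
        raise ValueError("need at least one map")
    ref = maps[0].z_pct
    for m in maps[1:]:
        if not m.z_pct.same_grid(ref):
            raise ValueError("all maps must share one grid")
    stack = np.stack([m.z_pct.data for m in maps])
    valid = ~np.isnan(stack)
    count = valid.sum(axis=0)
    total = np.where(valid, stack, 0.0).sum(axis=0)
    out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ref.with_data(out)
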