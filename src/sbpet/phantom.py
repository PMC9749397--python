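"""Paired pseudo-MRI / pseudo-PET brain phantoms with known ground truth.

The simulator emulates the statistical structure of a co-registered,
skull-stripped T1w-MRI / FDG-PET cohort: a three-tissue anatomy (CSF
ventricle core, WM shell, GM cortical ribbon) built from concentric
deformed ellipsoids, GM>WM>CSF uptake contrast, per-subject morphological
variability, atrophy (ventricular enlargement + cortical thinning),
multiplicative MRI bias fields, additive noise, and injectable focal
hypometabolic lesions with known location and magnitude.

Every phantom is deterministic given its seed, arrives aligned and
segmented (one shared grid), and carries its full ground truth: tissue
probability maps, an atlas-label parcellation and the lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "LesionSpec",
    "PhantomParams",
    "SubjectRecord",
    "generate_phantom",
    "apply_atrophy",
    "inject_lesion",
    "sample_bias_field",
]

# Anatomy constants, in units of normalized ellipsoidal radius (brain edge = 1).
_VENTRICLE_R0 = 0.22      # healthy ventricle boundary
_GM_INNER_R0 = 0.80       # healthy WM/GM boundary (cortical ribbon inner edge)
_VENTRICLE_GROWTH = 0.80  # fractional ventricle radius growth at atrophy = 1
_RIBBON_THINNING = 0.55   # fraction of GM ribbon thickness lost at atrophy = 1
_SEMI_AXES_FRAC = (0.42, 0.36, 0.40)  # ellipsoid semi-axes as fraction of grid


@dataclass(frozen=True)
class LesionSpec:
    """A spherical focal hypometabolic lesion.

    ``reduction`` is the fractional uptake loss: PET inside the lesion is
    multiplied by ``(1 - reduction)``.  With ``tissue_restrict`` the lesion
    applies only to gray-matter voxels (probability > 0.5), mimicking
    cortical hypometabolism.
    """

    center: tuple[int, int, int]
    radius_mm: float
    reduction: float
    tissue_restrict: bool = True

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("lesion radius_mm must be > 0")
        if not 0.0 < self.reduction <= 1.0:
            raise ValueError("lesion reduction must lie in (0, 1]")


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of one phantom subject."""

    grid_size: int = 64
    spacing_mm: float = 1.0
    atrophy: float = 0.0
    lesions: tuple[LesionSpec, ...] = ()
    uptake_ratios: tuple[float, float, float] = (3.0, 1.0, 0.2)  # GM, WM, CSF
    mri_means_sds: tuple[tuple[float, float], ...] = (
        (0.55, 0.03),  # GM
        (0.85, 0.03),  # WM
        (0.15, 0.02),  # CSF
    )
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    perturbation_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if not all(u > 0 for u in self.uptake_ratios):
            raise ValueError("uptake ratios must be strictly positive")
        if not 0.0 <= self.atrophy <= 1.0:
            raise ValueError("atrophy must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must lie in [0, 1)")
        object.__setattr__(self, "lesions", tuple(self.lesions))


@dataclass
class SubjectRecord:
    """Aligned bundle of one subject's volumes plus ground truth."""

    mri: Volume
    pet: Volume
    mask: Volume
    gm: Volume
    wm: Volume
    csf: Volume
    atlas: Volume | None = None
    lesion_mask: Volume | None = None
    group: str = "CN"
    params: PhantomParams | None = None

    def volumes(self) -> dict[str, Volume]:
        out = {
            "mri": self.mri,
            "pet": self.pet,
            "mask": self.mask,
            "gm": self.gm,
            "wm": self.wm,
            "csf": self.csf,
        }
        if self.atlas is not None:
            out["atlas"] = self.atlas
        if self.lesion_mask is not None:
            out["lesion"] = self.lesion_mask
        return out


def _smooth_field(shape: tuple[int, ...], coarse: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency standard-normal-ish field: coarse grid upsampled by cubic zoom."""
    g = rng.standard_normal((coarse,) * len(shape))
    zoom = [s / coarse for s in shape]
    return ndimage.zoom(g, zoom, order=3, mode="nearest", grid_mode=True)


def sample_bias_field(
    grid_size: int | tuple[int, int, int], amplitude: float, seed: int
) -> Volume:
    """Smooth multiplicative bias field with values in [1-amplitude, 1+amplitude].

    The field is a coarse-grid random field upsampled with cubic interpolation,
    centered and scaled so its grid mean is exactly 1 and its peak deviation
    is exactly ``amplitude``.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ValueError("bias amplitude must lie in [0, 1)")
    shape = (grid_size,) * 3 if np.isscalar(grid_size) else tuple(grid_size)
    if amplitude == 0.0:
        return Volume(np.ones(shape))
    rng = np.random.default_rng(seed)
    g = _smooth_field(shape, coarse=4, rng=rng)
    g -= g.mean()
    g /= np.max(np.abs(g))
    return Volume(1.0 + amplitude * g)


def _ramp(rho: np.ndarray, r: float, half_width: float) -> np.ndarray:
    """Linear 0->1 transition of total width 2*half_width centered at radius r."""
    return np.clip((rho - (r - half_width)) / (2.0 * half_width), 0.0, 1.0)


def _anatomy(params: PhantomParams, rho_pert: np.ndarray):
    """Tissue probability maps and brain mask from the perturbed radius field."""
    n = params.grid_size
    mean_axis = float(np.mean(_SEMI_AXES_FRAC)) * n
    delta = 1.0 / mean_axis  # 2-voxel partial-volume shell in rho units

    a = params.atrophy
    r_vent = _VENTRICLE_R0 * (1.0 + _VENTRICLE_GROWTH * a)
    ribbon = (1.0 - _GM_INNER_R0) * (1.0 - _RIBBON_THINNING * a)
    r_gm_inner = 1.0 - ribbon

    t_vent = _ramp(rho_pert, r_vent, delta)
    t_gm = _ramp(rho_pert, r_gm_inner, delta)
    t_brain = _ramp(rho_pert, 1.0, delta)

    csf = 1.0 - t_vent
    wm = t_vent * (1.0 - t_gm)
    gm = t_gm * (1.0 - t_brain)
    mask = (csf + wm + gm) > 0.0
    return gm, wm, csf, mask


def _atlas_octants(mask: np.ndarray) -> np.ndarray:
    """Partition the brain into 8 octant regions around the grid center."""
    n = mask.shape[0]
    c = (n - 1) / 2.0
    idx = np.indices(mask.shape)
    label = np.zeros(mask.shape, dtype=np.int16)
    for axis in range(3):
        label += (idx[axis] > c).astype(np.int16) << axis
    return np.where(mask, label + 1, 0).astype(np.int16)


def generate_phantom(params: PhantomParams) -> SubjectRecord:
    """Generate one paired MRI/PET phantom subject.

    Deterministic given ``params.seed``; all randomness (morphology, MRI
    texture, bias field, noise) flows through named substreams so that
    phantoms with the same seed but different atrophy or lesions share
    their noise realizations.
    """
    n = params.grid_size
    ss = np.random.SeedSequence(params.seed)
    rng_pert, rng_tex, ss_bias, rng_noise_mri, rng_noise_pet = [
        np.random.default_rng(c) if i != 2 else c
        for i, c in enumerate(ss.spawn(5))
    ]

    # Perturbed ellipsoidal radius field (per-subject morphology).
    center = (n - 1) / 2.0
    axes = np.array(_SEMI_AXES_FRAC) * n
    coords = np.indices((n, n, n), dtype=float)
    rho = np.sqrt(sum(((coords[i] - center) / axes[i]) ** 2 for i in range(3)))
    pert = _smooth_field((n, n, n), coarse=5, rng=rng_pert)
    pert = params.perturbation_amplitude * pert / max(np.max(np.abs(pert)), 1e-12)
    rho_pert = rho * (1.0 + pert)

    gm, wm, csf, mask = _anatomy(params, rho_pert)

    # PET: per-tissue uptake mixed by the probability maps.
    u_gm, u_wm, u_csf = params.uptake_ratios
    pet = gm * u_gm + wm * u_wm + csf * u_csf

    # MRI: per-tissue mean + smooth texture, mixed by the probability maps.
    mri = np.zeros_like(pet)
    for prob, (mu, sd) in zip((gm, wm, csf), params.mri_means_sds):
        tex = mu + sd * _smooth_field((n, n, n), coarse=8, rng=rng_tex)
        mri += prob * tex

    if params.bias_amplitude > 0:
        bias_seed = int(ss_bias.generate_state(1)[0] % (2**31))
        mri = mri * sample_bias_field(n, params.bias_amplitude, bias_seed).data

    if params.noise_sd > 0:
        mri = mri + rng_noise_mri.normal(0.0, params.noise_sd, mri.shape)
        pet = pet + rng_noise_pet.normal(0.0, params.noise_sd, pet.shape)
    pet = np.clip(pet, 0.0, None)
    mri = np.clip(mri, 0.0, None)

    affine = np.diag([params.spacing_mm] * 3 + [1.0])
    vol = lambda d: Volume(d, affine)
    record = SubjectRecord(
        mri=vol(mri.astype(np.float64)),
        pet=vol(pet.astype(np.float64)),
        mask=vol(mask.astype(np.uint8)),
        gm=vol(gm),
        wm=vol(wm),
        csf=vol(csf),
        atlas=vol(_atlas_octants(mask)),
        lesion_mask=vol(np.zeros(mask.shape, dtype=np.uint8)),
        group="CN",
        params=params,
    )

    for lesion in params.lesions:
        record = inject_lesion(record, lesion)
    if params.lesions:
        record.group = "AD"
    return record


def inject_lesion(record: SubjectRecord, lesion: LesionSpec) -> SubjectRecord:
    """Multiply PET uptake down inside a spherical lesion; MRI is unchanged.

    Models AD-like metabolic change without structural change.  The affected
    voxel set is recorded in ``lesion_mask``.  Raises ``ValueError`` when the
    lesion does not intersect the brain (or, if tissue-restricted, the GM).
    """
    spacing = record.pet.spacing
    idx = np.indices(record.pet.shape, dtype=float)
    d2 = sum(((idx[i] - lesion.center[i]) * spacing[i]) ** 2 for i in range(3))
    sphere = d2 <= lesion.radius_mm**2

    region = sphere & (record.mask.data > 0)
    if lesion.tissue_restrict:
        region &= record.gm.data > 0.5
    if not region.any():
        raise ValueError(
            "lesion sphere does not intersect the brain"
            + (" gray matter" if lesion.tissue_restrict else "")
        )

    pet = record.pet.data.copy()
    pet[region] *= 1.0 - lesion.reduction
    new_lesion_mask = (
        (record.lesion_mask.data > 0) | region
        if record.lesion_mask is not None
        else region
    )
    return replace(
        record,
        pet=record.pet.with_data(pet),
        lesion_mask=record.pet.with_data(new_lesion_mask.astype(np.uint8)),
    )


def apply_atrophy(record: SubjectRecord, atrophy: float) -> SubjectRecord:
    """Regenerate the subject at a new atrophy level.

    Atrophy deforms the anatomy (ventricular enlargement, cortical thinning);
    the PET uptake field is regenerated consistently with the deformed tissue
    maps — per-tissue metabolic rates are unchanged.  Requires the record to
    carry its generating parameters.
    """
    if not 0.0 <= atrophy <= 1.0:
        raise ValueError("atrophy must lie in [0, 1]")
    if record.params is None:
        raise ValueError("record does not carry phantom parameters")
    return generate_phantom(replace(record.params, atrophy=atrophy))


def make_cohort(
    n: int,
    *,
    grid_size: int = 64,
    atrophy_range: tuple[float, float] = (0.0, 0.8),
    lesion_prob: float = 0.0,
    lesion_reduction: float = 0.4,
    noise_sd: float = 0.02,
    bias_amplitude: float = 0.2,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Sample a cohort of phantoms with varying morphology/atrophy.

    Lesions (probability ``lesion_prob`` per subject) are placed at a random
    GM location found by rejection sampling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5BFE]))
    records = []
    for i in range(n):
        subj_seed = int(rng.integers(0, 2**31 - 1))
        atrophy = float(rng.uniform(*atrophy_range))
        lesions: list[LesionSpec] = []
        params = PhantomParams(
            grid_size=grid_size,
            atrophy=atrophy,
            noise_sd=noise_sd,
            bias_amplitude=bias_amplitude,
            seed=subj_seed,
        )
        if rng.uniform() < lesion_prob:
            probe = generate_phantom(params)
            lesions = [
                random_gm_lesion(
                    probe, rng, reduction=lesion_reduction, radius_mm=0.14 * grid_size
                )
            ]
            params = replace(params, lesions=tuple(lesions))
        records.append(generate_phantom(params))
    return records


def random_gm_lesion(
    record: SubjectRecord,
    rng: np.random.Generator,
    *,
    reduction: float,
    radius_mm: float,
) -> LesionSpec:
    """Draw a lesion centered on a random high-probability GM voxel.

    On coarse grids the ribbon may contain no fully pure GM voxels; the
    threshold then relaxes to 90% of the maximum GM probability (but never
    below the 0.5 majority level the lesion itself applies at).
    """
    g = np.asarray(record.gm.data)
    threshold = max(min(0.9, 0.9 * float(g.max())), 0.5)
    gm_idx = np.argwhere(g >= threshold)
    if len(gm_idx) == 0:
        raise ValueError("no gray-matter voxels to place a lesion in")
    center = tuple(int(v) for v in gm_idx[rng.integers(len(gm_idx))])
    return LesionSpec(center=center, radius_mm=radius_mm, reduction=reduction)
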