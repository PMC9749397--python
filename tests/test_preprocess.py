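"""Normalization-operator oracles: dilation, z-scoring, PET scaling, crop/pad, blur."""

import numpy as np
import pytest

from sbpet import (
    Volume,
    crop_pad_to_cube,
    dilate_mask,
    gaussian_blur,
    normalize_pet,
    preprocess_subject,
    znormalize_mri,
)
from sbpet.preprocess import SENTINEL


def brute_force_dilate(mask: np.ndarray, spacing, radius_mm: float) -> np.ndarray:
    """Independent oracle: threshold on exact per-voxel distance to the mask set."""
    pts = np.argwhere(mask > 0) * np.asarray(spacing)
    out = np.zeros_like(mask, dtype=bool)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * np.asarray(spacing)
        if np.min(np.linalg.norm(pts - p, axis=1)) <= radius_mm:
            out[idx] = True
    return out


class TestDilateMask:
    def test_zero_radius_identity(self, rng):
        m = Volume((rng.uniform(size=(8, 8, 8)) > 0.7).astype(np.uint8))
        out = dilate_mask(m, 0.0)
        np.testing.assert_array_equal(out.data, m.data)

    def test_single_voxel_lattice_count(self):
        m = np.zeros((25, 25, 25), dtype=np.uint8)
        m[12, 12, 12] = 1
        out = dilate_mask(Volume(m), 10.0)
        # oracle: integer lattice offsets with ||v|| <= 10
        r = np.arange(-12, 13)
        vv = np.stack(np.meshgrid(r, r, r, indexing="ij"))
        expected = (np.sum(vv**2, axis=0) <= 100).sum()
        assert out.data.sum() == expected

    def test_spacing_scaling(self):
        m = np.zeros((13, 13, 13), dtype=np.uint8)
        m[6, 6, 6] = 1
        iso2 = Volume(m, np.diag([2.0, 2.0, 2.0, 1.0]))
        out2 = dilate_mask(iso2, 10.0)
        out5 = dilate_mask(Volume(m), 5.0)  # 1 mm spacing, 5 mm radius
        np.testing.assert_array_equal(out2.data, out5.data)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            m = (rng.uniform(size=(12, 12, 12)) > 0.9).astype(np.uint8)
            if m.sum() == 0:
                m[5, 5, 5] = 1
            vol = Volume(m)
            for radius in (0.0, 2.5, 4.0):
                got = dilate_mask(vol, radius).data > 0
                want = brute_force_dilate(m, vol.spacing, radius)
                np.testing.assert_array_equal(got, want)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dilate_mask(Volume(np.zeros((4, 4, 4))), 2.0)


class TestZNormalize:
    def _toy(self, values):
        """4 tissue voxels with the given MRI values inside an 8^3 grid."""
        mri = np.zeros((8, 8, 8))
        gm = np.zeros_like(mri)
        for i, v in enumerate(values):
            mri[2 + i, 4, 4] = v
            gm[2 + i, 4, 4] = 1.0
        wm = np.zeros_like(mri)
        dmask = np.ones_like(mri, dtype=np.uint8)
        dmask[0] = 0  # one out-of-mask slab
        return Volume(mri), Volume(gm), Volume(wm), Volume(dmask)

    def test_population_sd_convention(self):
        mri, gm, wm, dmask = self._toy([1, 2, 3, 4])
        out = znormalize_mri(mri, gm, wm, dmask)
        got = sorted(out.data[gm.data > 0.5])
        want = [-1.3416407865, -0.4472135955, 0.4472135955, 1.3416407865]
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_sentinel_outside_dilated_mask(self):
        mri, gm, wm, dmask = self._toy([1, 2, 3, 4])
        out = znormalize_mri(mri, gm, wm, dmask)
        assert np.all(out.data[dmask.data == 0] == SENTINEL)

    def test_tissue_mean_zero_sd_one(self, phantom64_clean):
        rec = phantom64_clean
        dmask = dilate_mask(rec.mask, 10.0)
        out = znormalize_mri(rec.mri, rec.gm, rec.wm, dmask)
        tis = (rec.gm.data + rec.wm.data) > 0.5
        assert abs(out.data[tis].mean()) < 1e-9
        assert abs(out.data[tis].std() - 1.0) < 1e-9

    def test_constant_tissue_rejected(self):
        mri, gm, wm, dmask = self._toy([2, 2, 2, 2])
        with pytest.raises(ValueError, match="degenerate"):
            znormalize_mri(mri, gm, wm, dmask)


class TestNormalizePet:
    def _pet_1_to_100(self):
        pet = np.zeros((5, 5, 5))
        gm = np.zeros_like(pet)
        vals = np.arange(1.0, 101.0)
        flat_idx = np.unravel_index(np.arange(100), pet.shape)
        pet[flat_idx] = vals
        gm[flat_idx] = 1.0
        return Volume(pet), Volume(gm), Volume(np.zeros_like(pet))

    def test_top2pct_mean_oracle(self):
        pet, gm, wm = self._pet_1_to_100()
        out, c = normalize_pet(pet, gm, wm, blur_fwhm_mm=0.0)
        assert c == pytest.approx(99.5)  # mean{99, 100}
        # a voxel valued 199 would map to 2.0; check via the returned scale
        assert 199.0 / c == pytest.approx(2.0, abs=2e-2)
        assert out.data.max() == pytest.approx(100.0 / 99.5)

    def test_constant_pet_gives_unity(self):
        pet = Volume(np.full((6, 6, 6), 7.0))
        gm = Volume(np.ones((6, 6, 6)))
        wm = Volume(np.zeros((6, 6, 6)))
        out, c = normalize_pet(pet, gm, wm, blur_fwhm_mm=0.0)
        assert c == pytest.approx(7.0)
        np.testing.assert_allclose(out.data, 1.0)

    def test_scale_equivariance(self, phantom64_clean):
        rec = phantom64_clean
        out1, c1 = normalize_pet(rec.pet, rec.gm, rec.wm)
        scaled = rec.pet.with_data(rec.pet.data * 5.0)
        out2, c2 = normalize_pet(scaled, rec.gm, rec.wm)
        assert c2 == pytest.approx(5.0 * c1, rel=1e-12)
        np.testing.assert_allclose(out2.data, out1.data, rtol=1e-12)

    def test_renormalization_is_identity(self, phantom64_clean):
        rec = phantom64_clean
        out, _ = normalize_pet(rec.pet, rec.gm, rec.wm)
        _, c2 = normalize_pet(out, rec.gm, rec.wm)
        assert abs(c2 - 1.0) < 1e-9

    def test_all_zero_pet_rejected(self):
        pet = Volume(np.zeros((5, 5, 5)))
        gm = Volume(np.ones((5, 5, 5)))
        with pytest.raises(ValueError):
            normalize_pet(pet, gm, Volume(np.zeros((5, 5, 5))), blur_fwhm_mm=0.0)


class TestCropPad:
    def test_identity_when_already_cubic(self, rng):
        v = Volume(rng.normal(size=(16, 16, 16)))
        out = crop_pad_to_cube(v, 16)
        np.testing.assert_array_equal(out.data, v.data)
        np.testing.assert_array_equal(out.affine, v.affine)

    def test_mni_dims_to_192(self, rng):
        v = Volume(rng.normal(size=(197, 233, 189)).astype(np.float32))
        out = crop_pad_to_cube(v, 192, fill=0.0)
        assert out.shape == (192, 192, 192)
        # axis 0 cropped by 5 -> low 2 / high 3; axis 2 padded by 3 -> low 1 / high 2
        np.testing.assert_array_equal(out.data[:, :, 1:-2], v.data[2:194, 20:212, :])
        assert np.all(out.data[:, :, 0] == 0.0) and np.all(out.data[:, :, -2:] == 0.0)

    def test_world_coordinates_preserved(self, rng):
        affine = np.diag([1.5, 1.0, 2.0, 1.0])
        affine[:3, 3] = [10.0, -5.0, 3.0]
        v = Volume(rng.normal(size=(10, 20, 6)), affine)
        out = crop_pad_to_cube(v, 12, fill=0.0)
        # voxel (0,4,0) of the cropped/padded grid must map to the same world
        # point as its source voxel in the input
        world_out = out.affine @ np.array([1.0, 0.0, 3.0, 1.0])
        world_in = v.affine @ np.array([0.0, 4.0, 0.0, 1.0])
        np.testing.assert_allclose(world_out, world_in)

    def test_round_trip_on_overlap(self, rng):
        v = Volume(rng.normal(size=(9, 9, 9)))
        padded = crop_pad_to_cube(v, 15, fill=0.0)
        back = crop_pad_to_cube(padded, 9)
        np.testing.assert_array_equal(back.data, v.data)
        np.testing.assert_allclose(back.affine, v.affine)


class TestGaussianBlur:
    def test_zero_fwhm_identity(self, rng):
        v = Volume(rng.normal(size=(8, 8, 8)))
        np.testing.assert_array_equal(gaussian_blur(v, 0.0).data, v.data)

    def test_constant_volume_unchanged(self):
        v = Volume(np.full((12, 12, 12), 3.3))
        np.testing.assert_allclose(gaussian_blur(v, 3.0).data, 3.3, rtol=1e-12)

    def test_impulse_second_moment_matches_sigma(self):
        n = 41
        v = np.zeros((n, n, n))
        v[n // 2, n // 2, n // 2] = 1.0
        fwhm = 6.0
        out = gaussian_blur(Volume(v), fwhm).data
        sigma_expected = fwhm / (2 * np.sqrt(2 * np.log(2)))
        x = np.arange(n) - n // 2
        marg = out.sum(axis=(1, 2))
        var = np.sum(marg * x**2) / marg.sum()
        assert np.sqrt(var) == pytest.approx(sigma_expected, rel=0.02)

    def test_anisotropic_spacing_honored(self):
        n = 31
        v = np.zeros((n, n, n))
        v[n // 2, n // 2, n // 2] = 1.0
        affine = np.diag([2.0, 1.0, 1.0, 1.0])
        out = gaussian_blur(Volume(v, affine), 6.0).data
        x = np.arange(n) - n // 2
        m0 = out.sum(axis=(1, 2))
        m1 = out.sum(axis=(0, 2))
        sd0 = np.sqrt(np.sum(m0 * x**2) / m0.sum())  # in voxels, 2 mm each
        sd1 = np.sqrt(np.sum(m1 * x**2) / m1.sum())
        assert sd1 / sd0 == pytest.approx(2.0, rel=0.05)


class TestPreprocessSubject:
    def test_shapes_and_provenance(self, phantom32_noisy):
        ns = preprocess_subject(phantom32_noisy)
        assert ns.mri_z.shape == phantom32_noisy.mri.shape
        assert ns.pet_norm_constant > 0
        assert ns.provenance["dilate_mm"] == 10.0
        assert np.all(ns.mri_z.data[ns.dilated_mask.data == 0] == SENTINEL)
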