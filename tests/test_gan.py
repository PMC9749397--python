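"""Losses, augmentation, schedule, architecture and training-loop contracts."""

import numpy as np
import pytest

from sbpet import (
    ArchConfig,
    AugmentConfig,
    LossWeights,
    ModelBundle,
    TrainSchedule,
    adversarial_bce,
    augment_sample,
    count_parameters,
    discriminator_loss,
    generator_loss,
    lr_at_step,
    masked_l1,
    train_stage,
)
from sbpet.gan import _adversarial_bce_grad, _masked_l1_grad
from sbpet import nn
from sbpet.phantom import PhantomParams, generate_phantom
from sbpet.preprocess import preprocess_subject

LN2 = float(np.log(2.0))


class TestMaskedL1:
    def test_forced_arithmetic(self):
        pred = np.array([1.0, 3.0])
        target = np.array([2.0, 5.0])
        assert masked_l1(pred, target, np.ones(2)) == pytest.approx(1.5)
        assert masked_l1(pred, pred, np.ones(2)) == 0.0

    def test_mask_confinement(self, rng):
        pred = rng.normal(size=(4, 4, 4))
        target = rng.normal(size=(4, 4, 4))
        mask = rng.uniform(size=(4, 4, 4)) > 0.5
        base = masked_l1(pred, target, mask)
        pred2 = pred.copy()
        pred2[~mask] += 1e6
        assert masked_l1(pred2, target, mask) == base

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_l1(np.ones(3), np.ones(3), np.zeros(3))

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.normal(size=(4, 4, 4))
        target = rng.normal(size=(4, 4, 4))
        mask = rng.uniform(size=(4, 4, 4)) > 0.4
        g = _masked_l1_grad(pred, target, mask)
        h = 1e-6
        num = np.zeros_like(pred)
        for idx in np.ndindex(pred.shape):
            p1, p0 = pred.copy(), pred.copy()
            p1[idx] += h
            p0[idx] -= h
            num[idx] = (masked_l1(p1, target, mask) - masked_l1(p0, target, mask)) / (2 * h)
        np.testing.assert_allclose(g, num, atol=1e-5)


class TestAdversarialBCE:
    @pytest.mark.parametrize("label", ["real", "fake"])
    def test_half_probability_is_ln2(self, label):
        assert adversarial_bce(np.full((2, 3), 0.5), label) == pytest.approx(LN2)

    def test_confident_correct_is_small(self):
        assert adversarial_bce(np.ones((2, 2)), "real") < 1e-6

    def test_confident_wrong_is_large(self):
        assert adversarial_bce(np.ones((2, 2)), "fake") >= -np.log(1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.1, 0.9, size=(3, 3))
        for label in ("real", "fake"):
            g = _adversarial_bce_grad(p, label)
            h = 1e-7
            num = np.zeros_like(p)
            for idx in np.ndindex(p.shape):
                p1, p0 = p.copy(), p.copy()
                p1[idx] += h
                p0[idx] -= h
                num[idx] = (adversarial_bce(p1, label) - adversarial_bce(p0, label)) / (2 * h)
            np.testing.assert_allclose(g, num, rtol=1e-5)


class TestComposedLosses:
    def test_generator_perfect_prediction(self, rng):
        pred = rng.normal(size=(4, 4, 4))
        mask = np.ones_like(pred)
        w = LossWeights(lambda_adv=2.0)
        loss = generator_loss("sketcher", np.full(8, 0.5), pred, pred, mask, None, w)
        assert loss == pytest.approx(2.0 * LN2)

    def test_sketcher_reduces_to_l1_without_adv(self, rng):
        pred, target = rng.normal(size=(8,)), rng.normal(size=(8,))
        mask = np.ones(8)
        w = LossWeights(lambda_adv=0.0, lambda_l1_brain=100.0)
        loss = generator_loss("sketcher", np.full(4, 0.5), pred, target, mask, None, w)
        assert loss == pytest.approx(100.0 * masked_l1(pred, target, mask))

    def test_refiner_without_gm_weight_equals_sketcher(self, rng):
        pred, target = rng.normal(size=(8,)), rng.normal(size=(8,))
        mask, gm = np.ones(8), np.ones(8)
        w0 = LossWeights(lambda_l1_gm=0.0)
        d = np.full(4, 0.7)
        assert generator_loss("refiner", d, pred, target, mask, gm, w0) == pytest.approx(
            generator_loss("sketcher", d, pred, target, mask, None, w0)
        )

    def test_refiner_requires_gm_mask(self):
        with pytest.raises(ValueError):
            generator_loss("refiner", np.ones(2), np.ones(2), np.ones(2), np.ones(2), None, LossWeights())

    def test_discriminator_loss_values(self):
        assert discriminator_loss(np.full(4, 0.5), np.full(4, 0.5)) == pytest.approx(LN2)
        assert discriminator_loss(np.ones(4), np.zeros(4)) < 1e-6
        # perfectly fooled: maximal
        assert discriminator_loss(np.zeros(4), np.ones(4)) > 10.0


class TestLrSchedule:
    def test_full_schedule_values(self):
        sched = TrainSchedule.full_pretrain()
        assert lr_at_step(0, sched) == pytest.approx(1e-4)
        assert lr_at_step(19_999, sched) == pytest.approx(1e-4)
        assert lr_at_step(20_000, sched) == pytest.approx(1e-5)
        assert lr_at_step(50_000, sched) == pytest.approx(1e-6)
        assert lr_at_step(89_999, sched) == pytest.approx(1e-6)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            TrainSchedule(total_steps=100, decay_steps=(50, 40))
        with pytest.raises(ValueError):
            TrainSchedule(total_steps=100, decay_steps=(40, 150))


class TestAugmentation:
    def _sample(self, rec):
        return {
            "mri": np.asarray(rec.mri.data, np.float32),
            "pet": np.asarray(rec.pet.data, np.float32),
            "brain_mask": np.asarray(rec.mask.data),
            "gm_mask": (np.asarray(rec.gm.data) > 0.5).astype(np.uint8),
        }

    def test_disabled_is_identity(self, phantom32_noisy, rng):
        s = self._sample(phantom32_noisy)
        out = augment_sample(s, AugmentConfig.disabled(), rng)
        for k in s:
            np.testing.assert_array_equal(out[k], s[k])

    def test_mirror_is_involution(self, phantom32_noisy):
        s = self._sample(phantom32_noisy)
        cfg = AugmentConfig(p_mirror=1.0, p_affine=0.0, p_bias=0.0)
        once = augment_sample(s, cfg, np.random.default_rng(0))
        twice = augment_sample(once, cfg, np.random.default_rng(0))
        for k in s:
            np.testing.assert_array_equal(twice[k], s[k])

    def test_masks_binary_and_pet_nonnegative(self, phantom32_noisy):
        s = self._sample(phantom32_noisy)
        cfg = AugmentConfig()  # all augmentations possible
        out = augment_sample(s, cfg, np.random.default_rng(3))
        assert set(np.unique(out["brain_mask"])) <= {0, 1}
        assert set(np.unique(out["gm_mask"])) <= {0, 1}
        assert out["pet"].min() >= 0.0

    def test_deterministic_given_rng_state(self, phantom32_noisy):
        s = self._sample(phantom32_noisy)
        cfg = AugmentConfig()
        a = augment_sample(s, cfg, np.random.default_rng(42))
        b = augment_sample(s, cfg, np.random.default_rng(42))
        for k in s:
            np.testing.assert_array_equal(a[k], b[k])

    def test_bias_touches_only_brain_mri(self, phantom32_noisy):
        s = self._sample(phantom32_noisy)
        cfg = AugmentConfig(p_mirror=0.0, p_affine=0.0, p_bias=1.0)
        out = augment_sample(s, cfg, np.random.default_rng(1))
        outside = s["brain_mask"] == 0
        np.testing.assert_array_equal(out["mri"][outside], s["mri"][outside])
        np.testing.assert_array_equal(out["pet"], s["pet"])
        assert not np.array_equal(out["mri"], s["mri"])


class TestArchitecture:
    def test_generator_preserves_patch_shape(self, rng):
        net = nn.UNet3D(1, 4, 3, rng=rng)
        x = rng.normal(size=(1, 1, 8, 16, 16)).astype(np.float32)
        assert net.forward(x).shape == (1, 1, 8, 16, 16)

    def test_indivisible_patch_rejected(self, rng):
        net = nn.UNet3D(1, 4, 3, rng=rng)
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(1, 1, 6, 16, 16)))

    def test_unet_backward_matches_finite_differences(self):
        net = nn.UNet3D(1, 2, 2, rng=np.random.default_rng(1), dtype=np.float64)
        x = np.random.default_rng(2).normal(size=(1, 1, 4, 4, 4))
        dout = np.random.default_rng(3).normal(size=(1, 1, 4, 4, 4))
        net.forward(x)
        dx = net.backward(dout.copy())
        h = 1e-6
        flat = [(0, 0, 1, 2, 3), (0, 0, 3, 0, 1), (0, 0, 2, 2, 2)]
        for idx in flat:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            num = (np.sum(dout * net.forward(xp)) - np.sum(dout * net.forward(xm))) / (2 * h)
            assert dx[idx] == pytest.approx(num, abs=1e-6)

    def test_full_preset_parameter_count(self):
        count = count_parameters(ArchConfig.full())
        assert 1.5e8 <= count <= 2.5e8

    def test_bundle_count_matches_analytic(self):
        arch = ArchConfig(unet_depth=2, base_channels=4, patch_shape=(8, 16, 16), patchgan_layers=2)
        bundle = ModelBundle.initialize(arch, seed=0)
        assert bundle.count_parameters() == count_parameters(arch)


@pytest.fixture(scope="module")
def tiny_cohort():
    recs = [
        generate_phantom(PhantomParams(grid_size=16, seed=s, noise_sd=0.02, perturbation_amplitude=0.03))
        for s in range(4)
    ]
    return [preprocess_subject(r, dilate_mm=3.0) for r in recs]


def _tiny_arch():
    return ArchConfig(unet_depth=2, base_channels=4, patch_shape=(8, 16, 16),
                      patchgan_layers=2, scale_preset="desk")


class TestTrainStage:
    def test_deterministic_loss_trace(self, tiny_cohort):
        kw = dict(
            arch=_tiny_arch(), w=LossWeights(),
            sched=TrainSchedule.desk("pretrain", 10, seed=5),
            val_dataset=tiny_cohort[3:], augment_cfg=AugmentConfig(),
        )
        a = train_stage(tiny_cohort[:3], **kw)
        b = train_stage(tiny_cohort[:3], **kw)
        for ra, rb in zip(a.history, b.history):
            assert ra == rb

    def test_finetune_requires_init(self, tiny_cohort):
        with pytest.raises(ValueError):
            train_stage(
                tiny_cohort[:3], _tiny_arch(), LossWeights(),
                TrainSchedule.desk("finetune", 10, seed=5),
            )

    def test_finetune_continues_from_init(self, tiny_cohort):
        sched = TrainSchedule.desk("pretrain", 6, seed=5)
        pre = train_stage(tiny_cohort[:3], _tiny_arch(), LossWeights(), sched)
        fin = train_stage(
            tiny_cohort[:3], _tiny_arch(), LossWeights(),
            TrainSchedule.desk("finetune", 6, seed=6), init=pre,
        )
        assert fin.stage == "finetune"
        assert len(fin.history) == 6

    def test_checkpoint_round_trip(self, tiny_cohort, tmp_path):
        sched = TrainSchedule.desk("pretrain", 4, seed=2)
        bundle = train_stage(tiny_cohort[:2], _tiny_arch(), LossWeights(), sched)
        path = tmp_path / "ckpt.npz"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        x = np.random.default_rng(0).normal(size=(8, 16, 16)).astype(np.float32)
        np.testing.assert_allclose(bundle.predict_patch(x), loaded.predict_patch(x), atol=1e-6)
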