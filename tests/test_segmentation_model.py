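"""Segmentation losses (soft Dice, reconstruction, KL, composite) and the
encoder-decoder/VAE architecture contracts."""

import numpy as np
import pytest

from mgmtnet.nn import Tensor
from mgmtnet.segmentation_model import (SegConfig, build_seg_model, dice_loss,
                                        kl_loss, reconstruction_loss,
                                        seg_training_loss, soft_dice,
                                        total_loss)

TINY = SegConfig(input_height=32, input_width=32, base_channels=4, depth=2,
                 latent_dim=8, vae_reduce_channels=4)


class TestSoftDice:
    def test_identity_is_one(self):
        m = np.zeros((20, 20))
        m[:10, :10] = 1  # 100 ones
        assert soft_dice(m, m) == pytest.approx(200 / (200 + 1e-8))

    def test_disjoint_is_zero(self):
        a = np.zeros(10)
        a[:4] = 1
        b = np.zeros(10)
        b[5:] = 1
        assert soft_dice(a, b) == 0.0

    def test_four_pixel_half_probability_example(self):
        truth = np.array([1.0, 1.0, 0.0, 0.0])
        pred = np.full(4, 0.5)
        assert soft_dice(pred, truth) == pytest.approx(2 * 1 / (2 + 1 + 1e-8))
        assert soft_dice(pred, truth) == pytest.approx(0.6667, abs=1e-4)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = rng.random(50)
            b = (rng.random(50) > 0.5).astype(float)
            assert soft_dice(a, b) == pytest.approx(soft_dice(b, a))
            assert 0.0 <= soft_dice(a, b) <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_dice(np.zeros(3), np.zeros(4))


class TestDiceLoss:
    def test_complement_of_dice(self, rng):
        p = rng.random(30)
        t = (rng.random(30) > 0.5).astype(float)
        assert dice_loss(p, t) == pytest.approx(1 - soft_dice(p, t))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        p = Tensor(rng.uniform(0.1, 0.9, size=12), requires_grad=True)
        t = Tensor((rng.random(12) > 0.5).astype(float))
        loss = dice_loss(p, t)
        loss.backward()
        num = np.zeros_like(p.data)
        for i in range(12):
            eps = 1e-6
            old = p.data[i]
            p.data[i] = old + eps
            fp = float(dice_loss(p.detach(), t))
            p.data[i] = old - eps
            fm = float(dice_loss(p.detach(), t))
            p.data[i] = old
            num[i] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(p.grad, num, atol=1e-4)


class TestReconstructionLoss:
    def test_zero_offset_closed_form_symmetry(self, rng):
        a = rng.random((6, 6))
        assert reconstruction_loss(a, a) == 0.0
        assert reconstruction_loss(a + 0.3, a) == pytest.approx(0.09)
        b = rng.random((6, 6))
        assert reconstruction_loss(a, b) == pytest.approx(
            reconstruction_loss(b, a))


class TestKLLoss:
    def test_closed_forms(self):
        assert kl_loss(np.zeros(5), np.zeros(5)) == 0.0
        assert kl_loss(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)
        assert kl_loss(np.zeros(2), np.ones(2)) == pytest.approx(np.e - 2)

    def test_nonnegative(self, rng):
        for _ in range(20):
            mu = rng.normal(size=6)
            lv = rng.normal(size=6)
            assert kl_loss(mu, lv) >= 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            kl_loss(np.array([np.nan]), np.array([0.0]))


class TestTotalLoss:
    def test_weighted_sum(self):
        assert total_loss(0.5, 0.12, 0.3) == pytest.approx(0.542)
        assert total_loss(0.7, 0.0, 0.0) == pytest.approx(0.7)
        assert total_loss(0.7, 5.0, 9.0, w_l2=0, w_kl=0) == pytest.approx(0.7)

    def test_monotone_in_dice_term(self):
        assert total_loss(0.2, 1.0, 1.0) < total_loss(0.3, 1.0, 1.0)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            total_loss(-0.1, 0.0, 0.0)


class TestArchitecture:
    def test_output_shapes_and_ranges(self):
        model = build_seg_model(TINY, seed=0)
        model.eval()
        x = Tensor(np.random.default_rng(0).normal(
            size=(2, 1, 32, 32)).astype(np.float32))
        out = model(x)
        assert out.probability_map.shape == (2, 1, 32, 32)
        assert out.reconstruction.shape == (2, 1, 32, 32)
        assert out.mu.shape == (2, 8) and out.logvar.shape == (2, 8)
        p = out.probability_map.data
        assert (p > 0).all() and (p < 1).all()

    def test_default_latent_is_256(self):
        model = build_seg_model(SegConfig(input_height=32, input_width=32,
                                          base_channels=4), seed=0)
        model.eval()
        x = Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32) + 0.5)
        out = model(x)
        assert out.mu.shape == (1, 256)
        assert out.logvar.shape == (1, 256)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SegConfig(input_height=30, input_width=32, depth=2)

    def test_inference_deterministic(self):
        model = build_seg_model(TINY, seed=3)
        model.eval()
        x = Tensor(np.random.default_rng(1).normal(
            size=(1, 1, 32, 32)).astype(np.float32))
        a = model(x).probability_map.data
        b = model(x).probability_map.data
        np.testing.assert_array_equal(a, b)

    def test_one_optimizer_step_decreases_loss(self):
        from mgmtnet.nn import Adam

        model = build_seg_model(TINY, seed=5)
        rng = np.random.default_rng(7)
        x = Tensor(rng.normal(size=(1, 1, 32, 32)).astype(np.float32))
        y = np.zeros((1, 1, 32, 32), dtype=np.float32)
        y[0, 0, 10:20, 10:20] = 1
        y = Tensor(y)
        opt = Adam(model.parameters(), lr=1e-3)
        model.train()
        out = model(x, rng=np.random.default_rng(0))
        loss0, _ = seg_training_loss(model, out, x, y)
        model.zero_grad()
        loss0.backward()
        opt.step()
        out = model(x, rng=np.random.default_rng(0))
        loss1, _ = seg_training_loss(model, out, x, y)
        assert float(loss1.data) < float(loss0.data)

    def test_parameter_count_matches_closed_form_tiny(self):
        # layer-by-layer closed form for the tiny config, mirroring the
        # construction: counts depend only on the channel schedule
        c = TINY
        chans = [c.base_channels * 2 ** i for i in range(c.depth + 1)]

        def conv(cin, cout, k):
            return cout * (cin * k * k + 1)

        def resblock(ch):
            return 2 * conv(ch, ch, 3) + 2 * (2 * ch)  # two convs + two GN

        total = conv(c.in_channels, chans[0], 3)
        total += sum(resblock(ch) for ch in chans)           # encoder blocks
        total += sum(conv(chans[i], chans[i + 1], 3)
                     for i in range(c.depth))                # downsampling
        total += sum(conv(chans[i + 1], chans[i], 1) + resblock(chans[i])
                     for i in range(c.depth))                # seg decoder
        total += conv(chans[0], 1, 3)                        # seg head
        hb = c.input_height // 2 ** c.depth
        hv = hb // 2
        flat = c.vae_reduce_channels * hv * hv
        total += 2 * chans[-1]                               # vd GroupNorm
        total += conv(chans[-1], c.vae_reduce_channels, 3)   # vd conv
        total += flat * 2 * c.latent_dim + 2 * c.latent_dim  # fc to latent
        total += c.latent_dim * flat + flat                  # fc up
        total += conv(c.vae_reduce_channels, chans[-1], 1)   # vu conv
        total += sum(conv(chans[i + 1], chans[i], 1) + resblock(chans[i])
                     for i in range(c.depth))                # vae decoder
        total += conv(chans[0], c.in_channels, 3)            # recon head
        model = build_seg_model(c, seed=0)
        assert model.n_parameters() == total
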