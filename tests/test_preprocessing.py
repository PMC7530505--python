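"""Intensity standardization, z-scoring and rotation augmentation."""

import numpy as np
import pytest

from mgmtnet.preprocessing import (AugmentationPlan, DegenerateImageError,
                                   StandardScale, augment_rotations,
                                   compute_landmarks, fit_standard_scale,
                                   foreground_mode, standardize_image,
                                   zscore_foreground)


def image_from_fg(values, shape=None):
    """Embed a 1D foreground value list into a 2D image with zero border."""
    v = np.asarray(values, dtype=float)
    n = v.size
    side = int(np.ceil(np.sqrt(n))) + 2
    img = np.zeros((side, side))
    img.flat[side + 1:side + 1 + n] = v
    return img


class TestLandmarks:
    def test_linear_interpolation_convention(self):
        img = image_from_fg(np.arange(1, 101))
        lm = compute_landmarks(img, [1, 99])
        # sorted order statistics 1..100: p1 = 1.99, p99 = 99.01
        assert lm == pytest.approx([1.99, 99.01])

    def test_two_point_foreground_spans_range(self):
        lm = compute_landmarks(image_from_fg([10.0, 20.0]), [1, 99])
        assert 10 <= lm[0] < lm[1] <= 20

    def test_constant_foreground_errors(self):
        with pytest.raises(DegenerateImageError):
            compute_landmarks(image_from_fg([5.0] * 30), [1, 99])
        with pytest.raises(DegenerateImageError):
            compute_landmarks(np.zeros((5, 5)), [1, 99])


class TestStandardScale:
    def test_mean_of_landmarks(self):
        imgs = [image_from_fg(np.linspace(10, 110, 200)),
                image_from_fg(np.linspace(30, 130, 200))]
        scale = fit_standard_scale(imgs, [1, 99])
        lm1 = compute_landmarks(imgs[0], [1, 99])
        lm2 = compute_landmarks(imgs[1], [1, 99])
        assert scale.landmarks == pytest.approx(
            list((lm1 + lm2) / 2))

    def test_single_image_scale_is_own_landmarks(self):
        img = image_from_fg(np.linspace(5, 50, 100))
        scale = fit_standard_scale([img], [1, 99])
        assert scale.landmarks == pytest.approx(
            list(compute_landmarks(img, [1, 99])))

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        imgs = [image_from_fg(rng.uniform(1, 100, 150)) for _ in range(4)]
        a = fit_standard_scale(imgs, [1, 99]).landmarks
        b = fit_standard_scale(imgs[::-1], [1, 99]).landmarks
        assert a == pytest.approx(b)

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            StandardScale(percentiles=[99, 1])
        with pytest.raises(ValueError):
            StandardScale(percentiles=[0, 99])


class TestStandardizeImage:
    def test_single_segment_linear_map(self):
        # own landmarks ~ (0, 100)-ish grid; standard shifted by +10
        img = image_from_fg(np.linspace(0.5, 100, 400))
        own = compute_landmarks(img, [1, 99])
        scale = StandardScale(percentiles=[1, 99],
                              landmarks=list(own + 10.0))
        out = standardize_image(img, scale)
        fg = img > 0
        assert out[fg] == pytest.approx(img[fg] + 10.0, abs=1e-9)

    def test_identity_when_landmarks_match(self):
        img = image_from_fg(np.linspace(1, 60, 300))
        scale = StandardScale(percentiles=[1, 99],
                              landmarks=list(compute_landmarks(img, [1, 99])))
        out = standardize_image(img, scale)
        np.testing.assert_allclose(out, img, rtol=1e-12)

    def test_recomputed_landmarks_hit_standard(self):
        rng = np.random.default_rng(3)
        imgs = [image_from_fg(rng.gamma(4, 10, 500) + 1) for _ in range(3)]
        scale = fit_standard_scale(imgs, [1, 99])
        for img in imgs:
            out = standardize_image(img, scale)
            lm = compute_landmarks(out, [1, 99])
            np.testing.assert_allclose(lm, scale.landmarks, rtol=1e-6)

    def test_monotone_and_background_preserved(self):
        rng = np.random.default_rng(5)
        img = image_from_fg(rng.uniform(1, 50, 300))
        scale = StandardScale(percentiles=[1, 99], landmarks=[20.0, 90.0])
        out = standardize_image(img, scale)
        fg = img > 0
        order = np.argsort(img[fg])
        assert (np.diff(out[fg][order]) >= -1e-12).all()
        assert (out[~fg] == 0).all()

    def test_multi_landmark_schedule(self):
        rng = np.random.default_rng(8)
        pct = [1, 25, 50, 75, 99]
        imgs = [image_from_fg(rng.gamma(3, 5, 600) + 1) for _ in range(3)]
        scale = fit_standard_scale(imgs, pct)
        out = standardize_image(imgs[0], scale)
        # edge landmarks are exact; interior ones only up to the
        # order-statistic interpolation across segment boundaries
        got = compute_landmarks(out, pct)
        np.testing.assert_allclose([got[0], got[-1]],
                                   [scale.landmarks[0], scale.landmarks[-1]],
                                   rtol=1e-6)
        np.testing.assert_allclose(got, scale.landmarks, rtol=1e-3)


class TestZscore:
    def test_four_pixel_example(self):
        img = np.array([[0.0, 0.0], [2.0, 4.0]])
        out = zscore_foreground(img)
        np.testing.assert_allclose(out, [[0, 0], [-1, 1]])

    def test_defining_property(self):
        rng = np.random.default_rng(2)
        img = image_from_fg(rng.uniform(3, 90, 400))
        out = zscore_foreground(img)
        fg = img > 0
        assert abs(out[fg].mean()) < 1e-9
        assert abs(out[fg].std() - 1) < 1e-9
        assert (out[~fg] == 0).all()

    def test_all_background_errors(self):
        with pytest.raises(DegenerateImageError):
            zscore_foreground(np.zeros((4, 4)))


class TestAugmentation:
    def test_default_plan_yields_nine_pairs(self):
        img = np.zeros((32, 32))
        img[8:24, 8:24] = 1.5
        mask = (img > 1).astype(np.uint8)
        pairs = augment_rotations(img, mask)
        assert len(pairs) == 9
        angles = AugmentationPlan().angles_deg
        assert list(angles) == [-20, -15, -10, -5, 0, 5, 10, 15, 20]

    def test_zero_angle_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 20))
        mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        pairs = augment_rotations(img, mask)
        i0 = list(AugmentationPlan().angles_deg).index(0)
        np.testing.assert_array_equal(pairs[i0][0], img)
        np.testing.assert_array_equal(pairs[i0][1], mask)

    def test_masks_stay_binary_and_area_roughly_preserved(self):
        img = np.zeros((48, 48))
        img[10:38, 14:34] = 2.0
        mask = (img > 0).astype(np.uint8)
        area = int(mask.sum())
        assert area >= 50
        for im_r, mk_r in augment_rotations(img, mask):
            assert set(np.unique(mk_r)) <= {0, 1}
            assert abs(int(mk_r.sum()) - area) / area <= 0.1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment_rotations(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            AugmentationPlan(angles_deg=(-10, 10))  # missing 0
        with pytest.raises(ValueError):
            AugmentationPlan(angles_deg=(-10, 0, 20))  # asymmetric


class TestHistogramModeAlignment:
    """Synthetic reproduction of the two-peak density behavior: tissue
    peaks of differently scaled scans coincide after standardization."""

    def test_modes_align_after_standardization(self, phantom_batch):
        imgs = phantom_batch["images"]
        scale = fit_standard_scale(imgs)
        p99 = [np.percentile(im[im > 0], 99) for im in imgs]
        i, j = int(np.argmin(p99)), int(np.argmax(p99))
        before = abs(foreground_mode(imgs[i]) - foreground_mode(imgs[j]))
        after = abs(foreground_mode(standardize_image(imgs[i], scale))
                    - foreground_mode(standardize_image(imgs[j], scale)))
        assert before > 0.3          # raw scales genuinely disagree
        assert after < 0.3           # tissue peaks brought into register
        assert after < before / 2    # and at least halved
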