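import numpy as np
import pytest

import voxseg as vs
from voxseg.augment import AugmentConfig, geometric_augment, intensity_jitter, maybe_augment, roi_crop_window


def sample_pair(rng, shape=(4, 12, 12), n_mod=2):
    data = rng.normal(1.0, 0.3, size=(n_mod,) + shape).astype(np.float32)
    labels = np.zeros(shape, dtype=np.int16)
    labels[1:3, 4:8, 5:9] = 1
    return (
        vs.MultiModalVolume(data),
        vs.LabelVolume(labels, frozenset({0, 1})),
    )


IDENTITY = AugmentConfig(
    intensity_range=(1.0, 1.0),
    rotation_choices=(0,),
    rescale_range=(1.0, 1.0),
    flip_prob=0.0,
    crop_size=None,
    apply_prob=1.0,
)


class TestIntensityJitter:
    def test_collapsed_range_is_identity(self, rng):
        vol, _ = sample_pair(rng)
        out = intensity_jitter(vol, rng, (1.0, 1.0))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_ratio_constant_within_slice(self, rng):
        vol, _ = sample_pair(rng)
        out = intensity_jitter(vol, np.random.default_rng(0), (0.8, 1.2))
        ratio = out.data / vol.data
        for m in range(vol.n_modalities):
            for z in range(vol.data.shape[1]):
                r = ratio[m, z]
                assert r.std() < 1e-6
                assert 0.8 <= r.mean() <= 1.2

    def test_ratios_reproduce_seeded_stream(self, rng):
        vol, _ = sample_pair(rng)
        out = intensity_jitter(vol, np.random.default_rng(42), (0.8, 1.2))
        m, z = vol.data.shape[:2]
        expected = np.random.default_rng(42).uniform(0.8, 1.2, size=(m, z)).astype(np.float32)
        got = (out.data / vol.data)[:, :, 0, 0]
        np.testing.assert_allclose(got, expected, rtol=1e-5)


class TestGeometricAugment:
    def test_identity_settings_leave_both_untouched(self, rng):
        vol, lab = sample_pair(rng)
        out_v, out_l = geometric_augment(vol, lab, np.random.default_rng(0), IDENTITY)
        np.testing.assert_array_equal(out_v.data, vol.data)
        np.testing.assert_array_equal(out_l.labels, lab.labels)

    def test_four_quarter_turns_are_identity(self, rng):
        vol, lab = sample_pair(rng)
        cfg = AugmentConfig(
            rotation_choices=(90,), rescale_range=(1.0, 1.0), flip_prob=0.0, crop_size=None
        )
        v, l = vol, lab
        for _ in range(4):
            v, l = geometric_augment(v, l, np.random.default_rng(0), cfg)
        np.testing.assert_array_equal(v.data, vol.data)
        np.testing.assert_array_equal(l.labels, lab.labels)

    def test_rotation_and_flips_preserve_class_counts(self, rng):
        vol, lab = sample_pair(rng)
        cfg = AugmentConfig(rescale_range=(1.0, 1.0), flip_prob=1.0, crop_size=None)
        _, out_l = geometric_augment(vol, lab, np.random.default_rng(3), cfg)
        before = np.bincount(lab.labels.ravel(), minlength=2)
        after = np.bincount(out_l.labels.ravel(), minlength=2)
        np.testing.assert_array_equal(before, after)

    def test_labels_stay_in_class_set_under_rescale(self, rng):
        vol, lab = sample_pair(rng)
        cfg = AugmentConfig(rotation_choices=(0,), flip_prob=0.0, crop_size=None)
        for seed in range(5):
            _, out_l = geometric_augment(vol, lab, np.random.default_rng(seed), cfg)
            assert set(np.unique(out_l.labels)) <= {0, 1}
            assert out_l.labels.shape == lab.labels.shape

    def test_image_and_labels_share_geometric_parameters(self, rng):
        """Encode in-plane coordinates in both volumes; rotation+flips must
        move them identically (exact ops, no interpolation)."""
        z, y, x = 2, 8, 8
        coord = (np.arange(y)[:, None] * x + np.arange(x)[None, :]).astype(np.int16)
        labels = vs.LabelVolume(
            np.broadcast_to(coord, (z, y, x)).copy(), frozenset(range(y * x))
        )
        vol = vs.MultiModalVolume(
            np.broadcast_to(coord, (1, z, y, x)).astype(np.float32).copy()
        )
        cfg = AugmentConfig(rescale_range=(1.0, 1.0), flip_prob=0.5, crop_size=None)
        out_v, out_l = geometric_augment(vol, labels, np.random.default_rng(9), cfg)
        np.testing.assert_array_equal(out_v.data[0].astype(np.int16), out_l.labels)

    def test_determinism_under_seed(self, rng):
        vol, lab = sample_pair(rng)
        cfg = AugmentConfig(crop_size=(8, 8))
        a = geometric_augment(vol, lab, np.random.default_rng(5), cfg)
        b = geometric_augment(vol, lab, np.random.default_rng(5), cfg)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)


class TestRoiCrop:
    def test_window_contains_lesion_bbox(self, rng):
        _, lab = sample_pair(rng)
        for seed in range(20):
            y0, x0 = roi_crop_window(lab.labels, (6, 6), np.random.default_rng(seed))
            assert y0 <= 4 and y0 + 6 >= 8
            assert x0 <= 5 and x0 + 6 >= 9
            assert 0 <= y0 <= 6 and 0 <= x0 <= 6

    def test_oversized_bbox_centers_with_warning(self, rng, caplog):
        labels = np.zeros((2, 10, 10), dtype=np.int16)
        labels[:, 1:9, 1:9] = 1  # 8-wide bbox, 4-wide crop
        import logging

        with caplog.at_level(logging.WARNING, logger="voxseg.augment"):
            y0, x0 = roi_crop_window(labels, (4, 4), np.random.default_rng(0))
        assert "bounding box" in caplog.text
        assert (y0, x0) == (3, 3)  # centered on the lesion

    def test_no_lesion_is_unconstrained_but_valid(self, rng):
        labels = np.zeros((2, 10, 10), dtype=np.int16)
        y0, x0 = roi_crop_window(labels, (4, 4), rng)
        assert 0 <= y0 <= 6 and 0 <= x0 <= 6

    def test_crop_larger_than_plane_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            roi_crop_window(np.zeros((2, 4, 4), dtype=np.int16), (8, 8), rng)


class TestMaybeAugment:
    def test_probability_zero_is_passthrough(self, rng):
        sample = sample_pair(rng)
        cfg = AugmentConfig(apply_prob=0.0)
        out = maybe_augment(sample, np.random.default_rng(0), cfg)
        assert out is sample

    def test_probability_one_always_augments(self, rng):
        sample = sample_pair(rng)
        cfg = AugmentConfig(apply_prob=1.0, crop_size=None)
        for seed in range(5):
            out = maybe_augment(sample, np.random.default_rng(seed), cfg)
            assert out is not sample

    def test_half_probability_binomial(self, rng):
        sample = sample_pair(rng, shape=(1, 4, 4), n_mod=1)
        cfg = AugmentConfig(apply_prob=0.5, crop_size=None)
        gen = np.random.default_rng(123)
        n = 10000
        hits = sum(maybe_augment(sample, gen, cfg) is not sample for _ in range(n))
        se = (0.25 * n) ** 0.5
        assert abs(hits - n / 2) < 3 * se

    def test_invalid_apply_prob_rejected(self):
        with pytest.raises(ValueError, match="apply_prob"):
            AugmentConfig(apply_prob=1.5)
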