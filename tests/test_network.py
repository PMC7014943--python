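import math

import numpy as np
import pytest

import voxseg as vs
from voxseg.network import RefineUnit, load_checkpoint, save_checkpoint
from voxseg.nn import Upsample


def closed_form_parameter_count(c_in, widths, refine, n_classes):
    """Independent summation over the pinned layer list.

    Backbone: block1 = two 3x3x3 convs (c_in->w1->w1); blocks 2-4 = one
    strided 3x3x3 conv + two residual units of two 3x3x3 convs each. Every
    backbone conv carries a BatchNorm (2 affine params/channel, no conv
    bias). Decoder: four adaptive 1x1x1 convs (+BN), three refine units of
    two 1x1x1 convs and one 3x3x3 conv (+BN each), and a biased 1x1x1 head.
    """
    w1, w2, w3, w4 = widths
    total = 0
    # block 1
    total += 27 * c_in * w1 + 2 * w1
    total += 27 * w1 * w1 + 2 * w1
    prev = w1
    for w in (w2, w3, w4):
        total += 27 * prev * w + 2 * w  # strided down-sampling conv
        total += 2 * (2 * (27 * w * w + 2 * w))  # 2 ResBlocks x 2 convs
        prev = w
    for w in (w1, w2, w3, w4):  # adaptive layers
        total += w * refine + 2 * refine
    for _ in range(3):  # refine units
        total += 2 * (refine * refine + 2 * refine)  # two 1x1x1 branches
        total += 27 * refine * refine + 2 * refine  # fusing 3x3x3 conv
    total += refine * n_classes + n_classes  # head
    return total


class TestArchitectureCounts:
    def test_default_backbone_has_17_convs(self):
        _, desc = vs.build_model(vs.ModelConfig())
        assert desc.backbone_conv_count == 17

    def test_backbone_count_is_width_independent(self, tiny_model):
        _, desc, _ = tiny_model
        assert desc.backbone_conv_count == 17

    @pytest.mark.parametrize(
        "widths,refine", [((32, 64, 128, 256), 128), ((8, 16, 32, 64), 16)]
    )
    def test_total_parameters_match_closed_form(self, widths, refine):
        cfg = vs.ModelConfig(block_channels=widths, refine_channels=refine)
        _, desc = vs.build_model(cfg)
        expected = closed_form_parameter_count(4, widths, refine, 5)
        assert desc.total_parameters == expected
        assert desc.total_parameters == sum(r.n_params for r in desc.layers)

    def test_parameter_count_matches_live_arrays(self, tiny_model):
        model, desc, _ = tiny_model
        assert desc.total_parameters == sum(p.size for p in model.parameters())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            vs.ModelConfig(block_channels=(0, 64, 128, 256))
        with pytest.raises(ValueError):
            vs.ModelConfig(n_classes=1)


class TestFeatureShapes:
    def test_inplane_halving(self):
        shapes = vs.feature_shapes(vs.ModelConfig(), (12, 128, 128))
        assert shapes == [(12, 128, 128), (12, 64, 64), (12, 32, 32), (12, 16, 16)]

    def test_block1_equals_input(self):
        assert vs.feature_shapes(vs.ModelConfig(), (7, 96, 96))[0] == (7, 96, 96)

    def test_depth_downsample_halves_z(self):
        cfg = vs.ModelConfig(depth_downsample=True)
        assert vs.feature_shapes(cfg, (16, 128, 128))[3] == (2, 16, 16)


class TestForward:
    def test_output_grid_and_softmax(self, tiny_model, rng):
        model, _, cfg = tiny_model
        x = rng.normal(size=(1, 4, 2, 8, 8)).astype(np.float32)
        p = model.forward(x)
        assert p.shape == (1, cfg.n_classes, 2, 8, 8)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_block_channels_and_refined_resolution(self, tiny_model, rng):
        model, _, cfg = tiny_model
        x = rng.normal(size=(1, 4, 2, 16, 16)).astype(np.float32)
        _, feats = model.forward(x, return_features=True)
        for i, w in enumerate(cfg.block_channels):
            assert feats[f"block{i + 1}"].shape[1] == w
        assert feats["refined"].shape == (1, cfg.refine_channels, 2, 16, 16)

    def test_fully_convolutional_across_sizes(self, tiny_model, rng):
        model, desc, _ = tiny_model
        n_before = sum(p.size for p in model.parameters())
        model.forward(rng.normal(size=(1, 4, 2, 8, 8)).astype(np.float32))
        model.forward(rng.normal(size=(1, 4, 2, 16, 16)).astype(np.float32))
        assert sum(p.size for p in model.parameters()) == n_before == desc.total_parameters

    def test_indivisible_inplane_dims_rejected(self, tiny_model, rng):
        model, _, _ = tiny_model
        with pytest.raises(ValueError, match="multiple of 8"):
            model.forward(rng.normal(size=(1, 4, 2, 12, 8)).astype(np.float32))

    def test_eval_forward_deterministic(self, tiny_model, rng):
        model, _, _ = tiny_model
        x = rng.normal(size=(1, 4, 2, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_wrong_modality_count_rejected(self, tiny_model, rng):
        model, _, _ = tiny_model
        with pytest.raises(ValueError, match="modalit"):
            model.forward(rng.normal(size=(1, 3, 2, 8, 8)).astype(np.float32))


class TestRefineUnit:
    def test_fuses_to_fine_shape(self, rng):
        unit = RefineUnit(8, (1, 2, 2), rng=rng)
        fine = rng.normal(size=(1, 8, 3, 8, 8)).astype(np.float32)
        coarse = rng.normal(size=(1, 8, 3, 4, 4)).astype(np.float32)
        assert unit.forward(fine, coarse).shape == fine.shape

    def test_channel_mismatch_rejected(self, rng):
        unit = RefineUnit(8, (1, 2, 2), rng=rng)
        with pytest.raises(ValueError, match="channels"):
            unit.forward(
                rng.normal(size=(1, 4, 3, 8, 8)).astype(np.float32),
                rng.normal(size=(1, 8, 3, 4, 4)).astype(np.float32),
            )


class TestUpsample:
    def test_bilinear_ramp_matches_direct_formula(self):
        """x2 up-sample of a 2x2 ramp against the hand-evaluated half-pixel
        interpolation: out[i] at source coordinate (i+0.5)/2 - 0.5."""
        ramp = np.arange(4, dtype=np.float32).reshape(1, 1, 1, 2, 2)
        up = Upsample((1, 2, 2), "trilinear").forward(ramp)

        def interp1d(vals, i):
            src = (i + 0.5) / 2 - 0.5
            lo = math.floor(src)
            w = src - lo
            lo_c = min(max(lo, 0), len(vals) - 1)
            hi_c = min(max(lo + 1, 0), len(vals) - 1)
            return (1 - w) * vals[lo_c] + w * vals[hi_c]

        expected = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                rows = [interp1d(ramp[0, 0, 0, :, c], i) for c in range(2)]
                expected[i, j] = interp1d(rows, j)
        np.testing.assert_allclose(up[0, 0, 0], expected, atol=1e-6)

    def test_nearest_mode_duplicates(self):
        x = np.array([[1.0, 2.0]], dtype=np.float32).reshape(1, 1, 1, 1, 2)
        up = Upsample((1, 1, 2), "nearest").forward(x)
        np.testing.assert_array_equal(up[0, 0, 0, 0], [1, 1, 2, 2])

    def test_adjoint_property(self, rng):
        """backward is the exact transpose of forward: <Ux, y> == <x, U'y>."""
        up = Upsample((1, 2, 2), "trilinear")
        x = rng.normal(size=(1, 2, 2, 4, 4)).astype(np.float32)
        y = rng.normal(size=(1, 2, 2, 8, 8)).astype(np.float32)
        lhs = float((up.forward(x) * y).sum())
        rhs = float((x * up.backward(y)).sum())
        assert abs(lhs - rhs) < 1e-3


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, tiny_model, rng):
        model, _, _ = tiny_model
        x = rng.normal(size=(1, 4, 2, 8, 8)).astype(np.float32)
        before = model.forward(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, str(path))
        restored = load_checkpoint(str(path))
        np.testing.assert_array_equal(restored.forward(x), before)
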