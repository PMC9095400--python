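"""Architecture contracts of the learned denoisers."""

import numpy as np
import pytest

from usdenoise import nn
from usdenoise.models import (ArchitectureSpec, ResidualBlock, build_model,
                              build_plain_cnn, build_plain_unet, denoise,
                              forward_raw, load_checkpoint, save_checkpoint)
from usdenoise.models import _MaxPoolDown
from usdenoise.phantom import GrayImage


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestResidualBlock:
    def test_identity_under_zero_weights(self):
        block = ResidualBlock(4, np.random.default_rng(0))
        _zero_params(block)
        x = np.random.default_rng(1).normal(size=(1, 4, 8, 8))
        out = block(nn.Tensor(x))
        np.testing.assert_array_equal(out.data, np.asarray(x, out.data.dtype))

    def test_shape_preserved(self):
        block = ResidualBlock(4, np.random.default_rng(0))
        out = block(nn.Tensor(np.zeros((2, 4, 5, 7))))
        assert out.data.shape == (2, 4, 5, 7)

    def test_channel_mismatch_raises(self):
        block = ResidualBlock(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            block(nn.Tensor(np.zeros((1, 3, 8, 8))))

    def test_parameter_count_hand_tally(self):
        # two 3x3 CxC convs with biases, plus one PReLU slope per channel
        c = 4
        block = ResidualBlock(c, np.random.default_rng(0))
        expected = 2 * (3 * 3 * c * c + c) + c
        assert block.n_parameters() == expected


class TestBuildModel:
    def test_halve_double_rule_observed_in_forward(self):
        model = build_model(ArchitectureSpec.improved_unet(2, 8))
        forward_raw(model, np.zeros((64, 64)))
        assert model.net.last_encoder_shapes == [
            (64, 64, 8), (32, 32, 16), (16, 16, 32)]

    @pytest.mark.parametrize("size", [(64, 64), (96, 96), (64, 96)])
    def test_output_shape_equals_input_shape(self, size):
        model = build_model(ArchitectureSpec.improved_unet(2, 4))
        img = GrayImage(np.random.default_rng(0).uniform(0, 255, size))
        assert denoise(model, img).pixels.shape == size

    def test_non_multiple_size_padded_by_default(self):
        model = build_model(ArchitectureSpec.improved_unet(2, 4))
        out = forward_raw(model, np.zeros((70, 70)))
        assert out.shape == (70, 70)

    def test_non_multiple_size_rejected_in_strict_mode(self):
        model = build_model(ArchitectureSpec.improved_unet(2, 4))
        with pytest.raises(ValueError):
            forward_raw(model, np.zeros((70, 70)), strict=True)

    def test_init_deterministic_for_seed(self):
        a = build_model(ArchitectureSpec.improved_unet(2, 8, init_seed=5))
        b = build_model(ArchitectureSpec.improved_unet(2, 8, init_seed=5))
        for pa, pb in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(depth=0)
        with pytest.raises(ValueError):
            ArchitectureSpec(downsample="avg_pool")


class TestResidualLearning:
    def test_zero_recon_head_gives_identity_denoise(self):
        model = build_model(ArchitectureSpec.improved_unet(2, 4))
        _zero_params(model.net.final_conv)
        img = GrayImage(np.random.default_rng(2).uniform(0, 255, (64, 64)))
        out = denoise(model, img, quantize=False)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_unclipped_output_identity_bitwise(self):
        model = build_model(ArchitectureSpec.improved_unet(1, 4))
        _zero_params(model.net.final_conv)
        x = np.random.default_rng(3).uniform(0, 255, (32, 32))
        np.testing.assert_array_equal(forward_raw(model, x), x)


class TestPlainPresets:
    def test_plain_unet_reduces_to_traditional_structure(self):
        model = build_plain_unet(2, 8)
        net = model.net
        assert all(isinstance(d, _MaxPoolDown) for d in net.downs)
        blocks = net.enc_blocks + net.dec_blocks + [net.bottleneck]
        assert not any(isinstance(m, ResidualBlock) for m in blocks)
        assert net.rdubs is None
        assert isinstance(net.head, nn.Conv2d)    # no Recon stack
        assert model.residual_learning is False

    def test_parameter_counts_differ_between_presets(self):
        improved = build_model(ArchitectureSpec.improved_unet(2, 8))
        plain = build_plain_unet(2, 8)
        assert improved.n_parameters() != plain.n_parameters()

    def test_plain_cnn_shape_and_zero_head(self):
        model = build_plain_cnn(5, 16)
        out = forward_raw(model, np.random.default_rng(0).uniform(0, 255, (64, 64)))
        assert out.shape == (64, 64)
        _zero_params(model.net.final_conv)
        out = forward_raw(model, np.full((32, 32), 100.0))
        np.testing.assert_array_equal(out, np.zeros((32, 32)))

    def test_plain_cnn_depth_validated(self):
        with pytest.raises(ValueError):
            build_plain_cnn(1, 16)


class TestCheckpoints:
    def test_roundtrip_preserves_outputs(self, tmp_path):
        model = build_model(ArchitectureSpec.improved_unet(2, 4, init_seed=9))
        model.trained = True
        x = np.random.default_rng(1).uniform(0, 255, (32, 32))
        before = forward_raw(model, x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.trained
        assert loaded.kind == model.kind
        np.testing.assert_array_equal(forward_raw(loaded, x), before)

    def test_roundtrip_cnn(self, tmp_path):
        model = build_plain_cnn(3, 8, init_seed=2)
        path = tmp_path / "cnn.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        for pa, pb in zip(model.net.parameters(), loaded.net.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
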