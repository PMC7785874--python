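"""Residual blocks, attention-residual modules, and the U-Net builders."""

import numpy as np
import pytest

from raunet.errors import ConfigurationError, ShapeError
from raunet.ndnn import Tensor, no_grad
from raunet.ndnn.modules import AttentionModule, Conv, ResidualBlock
from raunet.network import (
    AttentionModuleSpec,
    NetworkSpec,
    RAUNet,
    ResidualBlockSpec,
    attention_module,
    build_raunet1,
    build_raunet2,
    count_parameters,
    load_checkpoint,
    residual_block,
    save_checkpoint,
)


def _straight_line_resblock(block, x):
    """Independent eval-mode recomputation of BN/ReLU/conv composition."""
    def bn(m, h):
        return (h - m.bn.running_mean) / np.sqrt(m.bn.running_var + m.bn.eps) \
            * m.bn.gamma.data + m.bn.beta.data

    def conv_same(h, w, b):
        k = w.shape[:3]
        pads = [(kk // 2, kk // 2) for kk in k] + [(0, 0)]
        hp = np.pad(h, pads)
        out = np.zeros(h.shape[:-1] + (w.shape[-1],), dtype=np.float32)
        for dx in range(k[0]):
            for dy in range(k[1]):
                for dz in range(k[2]):
                    view = hp[dx:dx + h.shape[0], dy:dy + h.shape[1], dz:dz + h.shape[2]]
                    out += view @ w[dx, dy, dz]
        return out + b

    h = x
    for m in (block.set1, block.set2, block.set3):
        h = bn(m, h)
        h = np.maximum(h, 0.0)
        w = m.conv.w.data
        if w.ndim == 3:  # 1-kernel conv stored as (1,1,1,ci,co) is always 5D here
            raise AssertionError
        h = conv_same(h, w, m.conv.b.data)
    identity = x if block.identity is None else (
        conv_same(x, block.identity.w.data, block.identity.b.data)
    )
    return identity + h


class TestResidualBlock:
    def test_zeroed_branch_reduces_to_identity_path(self, rng):
        block = ResidualBlock(3, 4, 4, 3, np.random.default_rng(0))
        block.set3.conv.w.data[...] = 0.0
        block.set3.conv.b.data[...] = 0.0
        block.eval()
        x = Tensor(rng.normal(size=(1, 4, 4, 2, 4)).astype(np.float32))
        assert np.array_equal(block(x).data, x.data)

    def test_zeroed_branch_uses_projection_when_channels_differ(self, rng):
        block = ResidualBlock(3, 3, 6, 3, np.random.default_rng(0))
        block.set3.conv.w.data[...] = 0.0
        block.set3.conv.b.data[...] = 0.0
        block.eval()
        x = Tensor(rng.normal(size=(1, 4, 4, 2, 3)).astype(np.float32))
        expected = block.identity(x)
        assert np.array_equal(block(x).data, expected.data)

    def test_forward_matches_straight_line_recomputation(self, rng):
        block = ResidualBlock(3, 2, 8, 3, np.random.default_rng(3))
        block.eval()
        x = rng.normal(size=(4, 4, 4, 2)).astype(np.float32)
        with no_grad():
            got = block(Tensor(x[None])).data[0]
        expect = _straight_line_resblock(block, x)
        np.testing.assert_allclose(got, expect, rtol=1e-4, atol=1e-4)

    def test_table_row_shape_preserved(self):
        # encoder row Res1: 112x112x16 grid, 32 channels in and out
        model = build_raunet2(NetworkSpec(dimensionality=3, base_channels=32))
        x = Tensor(np.zeros((1, 112, 112, 16, 32), dtype=np.float32))
        model.res1.eval()
        with no_grad():
            out = model.res1(x)
        assert out.shape == (1, 112, 112, 16, 32)

    def test_functional_wrapper_validates_channels(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 4, 2, 3)).astype(np.float32))
        with pytest.raises(ConfigurationError):
            residual_block(x, ResidualBlockSpec(in_channels=5, out_channels=5))

    @pytest.mark.parametrize("bad", [dict(in_channels=0, out_channels=4),
                                     dict(in_channels=4, out_channels=4, kernel_size=2)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ResidualBlockSpec(**bad)


class TestAttentionModule:
    @pytest.mark.parametrize("depth", [0, 1, 2])
    def test_zero_mask_reduces_to_trunk_bitwise(self, rng, depth):
        mod = AttentionModule(3, 4, depth, 3, np.random.default_rng(depth))
        mod.eval()
        x = Tensor(rng.normal(size=(1, 8, 8, 4, 4)).astype(np.float32))
        with no_grad():
            trunk = mod.trunk(x)
            mod.soft_mask_override = 0.0
            out = mod(x)
        assert np.array_equal(out.data, trunk.data)

    def test_unit_mask_doubles_trunk(self, rng):
        mod = AttentionModule(3, 4, 1, 3, np.random.default_rng(5))
        mod.eval()
        x = Tensor(rng.normal(size=(1, 8, 8, 4, 4)).astype(np.float32))
        with no_grad():
            trunk = mod.trunk(x)
            mod.soft_mask_override = 1.0
            out = mod(x)
        np.testing.assert_allclose(out.data, 2.0 * trunk.data, rtol=1e-6)

    def test_soft_mask_values_lie_in_unit_interval(self, rng):
        # the sigmoid bounds hold for any weights; float32 saturates to the
        # closed endpoints for large logits, so the strict-interior check
        # uses damped output weights
        mod = AttentionModule(3, 4, 2, 3, np.random.default_rng(9))
        mod.eval()
        x = Tensor(rng.normal(scale=3.0, size=(1, 8, 8, 4, 4)).astype(np.float32))
        with no_grad():
            m = mod.soft_mask(x).data
        assert m.min() >= 0.0 and m.max() <= 1.0
        mod.mask_out2.w.data *= 0.01
        mod.mask_out2.b.data *= 0.01
        with no_grad():
            m = mod.soft_mask(x).data
        assert m.min() > 0.0 and m.max() < 1.0

    def test_output_shape_equals_trunk_shape(self, rng):
        x = Tensor(rng.normal(size=(1, 8, 8, 4, 6)).astype(np.float32))
        out = attention_module(x, AttentionModuleSpec(channels=6, depth=2), seed=1)
        assert out.shape == x.shape

    def test_indivisible_depth_rejected(self, rng):
        x = Tensor(rng.normal(size=(1, 6, 6, 3, 4)).astype(np.float32))
        with pytest.raises((ConfigurationError, ValueError)):
            attention_module(x, AttentionModuleSpec(channels=4, depth=2), seed=1)


class TestBuilders:
    def test_tiny_3d_forward_is_valid_probability_grid(self):
        model = build_raunet2(NetworkSpec(dimensionality=3, base_channels=4, seed=0))
        model.eval()
        x = Tensor(np.zeros((1, 64, 64, 16, 1), dtype=np.float32))
        with no_grad():
            out = model(x)
        assert out.shape == (1, 64, 64, 16, 1)
        assert np.isfinite(out.data).all()
        assert 0.0 < out.data.min() and out.data.max() < 1.0

    @pytest.mark.parametrize("spatial", [(256, 256), (224, 224)])
    def test_2d_builder_accepts_admissible_planes(self, spatial):
        model = build_raunet1(NetworkSpec(dimensionality=2, base_channels=4, seed=0))
        model.eval()
        x = Tensor(np.zeros((1,) + spatial + (1,), dtype=np.float32))
        with no_grad():
            out = model(x)
        assert out.shape == (1,) + spatial + (1,)
        assert 0.0 < out.data.min() and out.data.max() < 1.0

    def test_2d_and_3d_share_channel_progression(self):
        taps2 = build_raunet1(NetworkSpec(dimensionality=2, base_channels=4, seed=0)) \
            .probe_shapes((64, 64))
        taps3 = build_raunet2(NetworkSpec(dimensionality=3, base_channels=4, seed=0)) \
            .probe_shapes((64, 64, 16))
        names = ["Conv1", "Res1", "Res2", "Res3", "Res4", "Res5", "Res6",
                 "Att1", "Res7", "Att2", "Res8", "Att3", "Res9", "Att4",
                 "Res10", "Conv2", "Conv3"]
        for name in names:
            assert taps2[name][-1] == taps3[name][-1]
        assert [taps3[n][-1] for n in ["Conv1", "Res2", "Res3", "Res4", "Res5"]] == \
            [4, 8, 16, 32, 64]

    def test_wrong_dimensionality_rejected(self):
        with pytest.raises(ConfigurationError):
            build_raunet2(NetworkSpec(dimensionality=2))
        with pytest.raises(ConfigurationError):
            build_raunet1(NetworkSpec(dimensionality=3))

    def test_indivisible_input_rejected(self):
        model = build_raunet2(NetworkSpec(dimensionality=3, base_channels=4))
        with pytest.raises(ConfigurationError):
            model(Tensor(np.zeros((1, 48, 48, 16, 1), dtype=np.float32)))

    def test_wrong_rank_rejected(self):
        model = build_raunet2(NetworkSpec(dimensionality=3, base_channels=4))
        with pytest.raises(ShapeError):
            model(Tensor(np.zeros((1, 64, 64, 1), dtype=np.float32)))


class TestParameterCounting:
    def test_single_3d_conv_counts_weights_plus_bias(self):
        conv = Conv(3, 1, 1, 3, np.random.default_rng(0))
        assert count_parameters(conv) == 28  # 27 weights + 1 bias

    def test_count_is_monotone_in_width(self):
        quarter = count_parameters(build_raunet2(NetworkSpec(dimensionality=3, base_channels=8)))
        full = count_parameters(build_raunet2(NetworkSpec(dimensionality=3, base_channels=32)))
        assert quarter < full

    def test_batch_norm_scales_are_counted(self):
        from raunet.ndnn.modules import BatchNorm

        assert count_parameters(BatchNorm(7)) == 14


class TestCheckpointing:
    def test_roundtrip_preserves_forward(self, tmp_path, rng):
        spec = NetworkSpec(dimensionality=3, base_channels=4, seed=11)
        model = build_raunet2(spec)
        model.eval()
        x = Tensor(rng.normal(size=(1, 32, 32, 16, 1)).astype(np.float32))
        with no_grad():
            before = model(x).data
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        restored.eval()
        with no_grad():
            after = restored(x).data
        assert restored.spec == spec
        assert np.array_equal(before, after)

    def test_spec_yaml_roundtrip(self):
        spec = NetworkSpec(dimensionality=2, base_channels=16, input_shape=(256, 256))
        again = NetworkSpec.from_dict(spec.to_dict())
        assert again == spec and again.spec_hash() == spec.spec_hash()
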