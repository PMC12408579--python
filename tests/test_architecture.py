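"""Backbone, attention, pyramid and full-model structure tests."""

from dataclasses import replace

import numpy as np
import pytest

from tcdnet import _tensor as T
from tcdnet._tensor import Tensor
from tcdnet.attention import ChannelAttention, HybridAttention, SpatialAttention
from tcdnet.backbone import BackboneConfig, Block, Downsample, PartialNeXt
from tcdnet.fpn import AdaptiveFeatureMixer, FeaturePyramid, FPNConfig
from tcdnet.model import ModelConfig, TCDNet, profile
from tcdnet.nn import Conv2d, PartialConv2d

RNG = np.random.default_rng(42)


def rand(*shape):
    return Tensor(RNG.normal(0, 1, shape).astype(np.float32))


class TestPartialConv:
    def test_untouched_slice_passes_through(self):
        pc = PartialConv2d(8, 3, np.random.default_rng(0), ratio=0.25)
        x = rand(8, 6, 6)
        out = pc(x)
        np.testing.assert_array_equal(out.data[2:], x.data[2:])

    def test_ratio_one_is_dense_conv(self):
        rng = np.random.default_rng(1)
        pc = PartialConv2d(4, 3, rng, ratio=1.0)
        x = rand(4, 5, 5)
        ref = T.conv2d(x, pc.conv.weight, pc.conv.bias, padding=1)
        np.testing.assert_allclose(pc(x).data, ref.data)

    def test_equals_slice_conv_concat_composition(self):
        rng = np.random.default_rng(2)
        pc = PartialConv2d(8, 7, rng, ratio=0.25)
        x = rand(8, 8, 8)
        head = T.conv2d(x[:2], pc.conv.weight, pc.conv.bias, padding=3)
        ref = np.concatenate([head.data, x.data[2:]], axis=0)
        np.testing.assert_allclose(pc(x).data, ref)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            PartialConv2d(10, 7, np.random.default_rng(0), ratio=0.25)

    def test_parameter_count_c640(self):
        pc = PartialConv2d(640, 7, np.random.default_rng(0), ratio=0.25)
        assert pc.n_params() == 7 * 7 * 160 * 160 + 160 == 1_254_560


class TestBlock:
    def test_shape_preserved(self):
        blk = Block(16, BackboneConfig(dims=(16,)), np.random.default_rng(0))
        x = rand(16, 8, 8)
        assert blk(x).shape == (16, 8, 8)

    def test_zero_projection_gives_identity(self):
        blk = Block(16, BackboneConfig(), np.random.default_rng(0))
        blk.fc2.weight.data[:] = 0
        blk.fc2.bias.data[:] = 0
        x = rand(16, 8, 8)
        np.testing.assert_allclose(blk(x).data, x.data, atol=1e-6)

    @pytest.mark.parametrize("c", [16, 80])
    def test_baseline_block_param_count_formula(self, c):
        # independent enumeration: dw 49c+c, LN 2c, expand 4c^2+4c,
        # GRN 8c, project 4c^2+c  →  8c^2 + 65c
        blk = Block(c, BackboneConfig(use_pconv=False), np.random.default_rng(0))
        assert blk.n_params() == 8 * c * c + 65 * c


class TestDownsample:
    def test_halves_space_doubles_channels(self):
        ds = Downsample(160, 320, np.random.default_rng(0))
        assert ds(rand(160, 8, 8)).shape == (320, 4, 4)

    def test_odd_size_rejected(self):
        ds = Downsample(4, 8, np.random.default_rng(0))
        with pytest.raises(ValueError, match="even"):
            ds(rand(4, 5, 6))


class TestBackbone:
    @pytest.fixture(scope="class")
    def tiny(self):
        cfg = BackboneConfig(depths=(1, 1, 1, 1), dims=(8, 16, 32, 64))
        return PartialNeXt(cfg, np.random.default_rng(0))

    def test_pyramid_shapes(self, tiny):
        feats = tiny(rand(3, 64, 64))
        assert feats["C2"].shape == (8, 16, 16)
        assert feats["C3"].shape == (16, 8, 8)
        assert feats["C4"].shape == (32, 4, 4)
        assert feats["C5"].shape == (64, 2, 2)

    def test_indivisible_input_rejected(self, tiny):
        with pytest.raises(ValueError, match="pad"):
            tiny(rand(3, 60, 64))

    def test_deterministic(self, tiny):
        x = rand(3, 32, 32)
        a = tiny(x)["C5"].data
        b = tiny(x)["C5"].data
        np.testing.assert_array_equal(a, b)


class TestChannelAttention:
    def test_spatially_constant_input_gives_uniform_gate(self):
        ca = ChannelAttention(4, np.random.default_rng(0))
        x = Tensor(np.tile(RNG.normal(size=(8, 1, 1)), (1, 9, 9)).astype(np.float32))
        out = ca(x)
        gate = out.data / np.where(np.abs(x.data) > 1e-8, x.data, 1.0)
        for c in range(8):
            vals = gate[c][np.abs(x.data[c]) > 1e-8]
            if vals.size:
                assert vals.std() < 1e-5

    def test_gate_bounds_and_shape(self):
        ca = ChannelAttention(4, np.random.default_rng(0))
        x = rand(8, 12, 12)
        out = ca(x)
        assert out.shape == x.shape
        assert (np.abs(out.data) <= np.abs(x.data) + 1e-6).all()

    def test_local_size_clamped_with_warning(self):
        ca = ChannelAttention(32, np.random.default_rng(0))
        with pytest.warns(UserWarning, match="clamping"):
            ca(rand(4, 8, 8))


class TestSpatialAttention:
    def test_map_invariant_to_channel_permutation(self):
        sa = SpatialAttention(np.random.default_rng(0))
        x = RNG.normal(size=(4, 5, 5)).astype(np.float32)
        out1 = sa(Tensor(x)).data / x
        perm = x[[2, 0, 3, 1]]
        out2 = sa(Tensor(perm)).data / perm
        np.testing.assert_allclose(out1[0], out2[0], rtol=1e-5, atol=1e-6)

    def test_output_bounded_by_input(self):
        sa = SpatialAttention(np.random.default_rng(0))
        x = rand(4, 6, 6)
        assert (np.abs(sa(x).data) <= np.abs(x.data) + 1e-6).all()


class TestHybridAttention:
    def test_residual_definition(self):
        ha = HybridAttention(4, np.random.default_rng(0))
        x = rand(8, 8, 8)
        composed = ha.spatial(ha.channel(x))
        np.testing.assert_allclose(ha(x).data, composed.data + x.data, atol=1e-6)

    def test_param_count_is_23(self):
        ha = HybridAttention(8, np.random.default_rng(0))
        assert ha.n_params() == 23

    def test_zeroed_convs_give_half_gates(self):
        ha = HybridAttention(4, np.random.default_rng(0))
        ha.channel.w1d.data[:] = 0
        ha.channel.b1d.data = np.zeros((), np.float32)
        ha.spatial.conv.weight.data[:] = 0
        ha.spatial.conv.bias.data[:] = 0
        x = rand(8, 8, 8)
        # both gates are sigmoid(0)=0.5 → HA(x) = x/4 + x
        np.testing.assert_allclose(ha(x).data, 1.25 * x.data, rtol=1e-5, atol=1e-6)


class TestAFM:
    @pytest.fixture(scope="class")
    def afm(self):
        return AdaptiveFeatureMixer(16, 4, np.random.default_rng(0))

    def test_weight_in_open_interval(self, afm):
        w = afm.weight(rand(16, 5, 5), rand(16, 5, 5))
        assert (w.data > 0).all() and (w.data < 1).all()

    def test_zeroed_afm_averages(self, afm):
        for p in afm.parameters():
            p.data = np.zeros_like(p.data)
        f1, f2 = rand(16, 5, 5), rand(16, 5, 5)
        np.testing.assert_allclose(afm(f1, f2).data, (f1.data + f2.data) / 2,
                                   rtol=1e-5, atol=1e-6)

    def test_equal_inputs_fixed_point(self):
        afm = AdaptiveFeatureMixer(16, 4, np.random.default_rng(1))
        f = rand(16, 4, 4)
        np.testing.assert_allclose(afm(f, f).data, f.data, rtol=1e-5, atol=1e-6)

    def test_large_bias_selects_f1(self):
        afm = AdaptiveFeatureMixer(8, 4, np.random.default_rng(2))
        afm.sp2.bias.data[:] = 50.0
        f1, f2 = rand(8, 4, 4), rand(8, 4, 4)
        np.testing.assert_allclose(afm(f1, f2).data, f1.data, atol=1e-4)

    def test_output_between_inputs(self):
        afm = AdaptiveFeatureMixer(8, 4, np.random.default_rng(3))
        f1, f2 = rand(8, 4, 4), rand(8, 4, 4)
        out = afm(f1, f2).data
        lo = np.minimum(f1.data, f2.data)
        hi = np.maximum(f1.data, f2.data)
        assert (out >= lo - 1e-6).all() and (out <= hi + 1e-6).all()

    def test_param_count_default_width(self):
        afm = AdaptiveFeatureMixer(256, 64, np.random.default_rng(0))
        assert afm.n_params() == 66_176

    def test_shape_mismatch_rejected(self, afm):
        with pytest.raises(ValueError, match="shape"):
            afm.weight(rand(16, 5, 5), rand(16, 4, 4))


class TestFeaturePyramid:
    IN = {"C2": 8, "C3": 16, "C4": 32, "C5": 64}

    def feats(self):
        return {"C2": rand(8, 16, 16), "C3": rand(16, 8, 8),
                "C4": rand(32, 4, 4), "C5": rand(64, 2, 2)}

    def test_output_channels_and_strides(self):
        fp = FeaturePyramid(self.IN, FPNConfig(channels=24, afm_hidden=8),
                            np.random.default_rng(0))
        out = fp(self.feats())
        assert {k: v.shape for k, v in out.items()} == {
            "P2": (24, 16, 16), "P3": (24, 8, 8), "P4": (24, 4, 4), "P5": (24, 2, 2)}

    def test_disabled_afm_is_vanilla_fpn(self):
        fp = FeaturePyramid(self.IN, FPNConfig(channels=24, afm_enabled=False),
                            np.random.default_rng(0))
        feats = self.feats()
        out = fp(feats)
        # hand composition: lateral + upsampled
        lat = {lv: T.conv2d(feats[lv], conv.weight, conv.bias)
               for lv, conv in zip(("C2", "C3", "C4", "C5"), fp.laterals)}
        p4 = lat["C4"].data + T.bilinear_resize(lat["C5"], 4, 4).data
        np.testing.assert_allclose(out["P4"].data, p4, rtol=1e-5, atol=1e-6)

    def test_afm_overhead_parameter_count(self):
        rng = np.random.default_rng(0)
        with_afm = FeaturePyramid(self.IN, FPNConfig(channels=256, afm_hidden=64),
                                  np.random.default_rng(0))
        without = FeaturePyramid(self.IN, FPNConfig(channels=256, afm_enabled=False),
                                 np.random.default_rng(0))
        assert with_afm.n_params() - without.n_params() == 3 * 66_176 == 198_528


class TestModel:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        cfg = ModelConfig(
            backbone=BackboneConfig(depths=(1, 1, 1, 1), dims=(8, 16, 32, 64)),
            fpn=FPNConfig(channels=16, afm_hidden=4),
            input_size=(64, 64),
        )
        return TCDNet(cfg, rng=0)

    def test_probability_map_contract(self, tiny_model):
        pmap = tiny_model(RNG.normal(0, 1, (3, 64, 64)).astype(np.float32))
        assert pmap.values.shape == (64, 64)
        assert (pmap.values > 0).all() and (pmap.values < 1).all()
        np.testing.assert_allclose(
            pmap.values, 1 / (1 + np.exp(-pmap.logits)), rtol=1e-6)

    def test_zero_heads_give_bias_sum_logits(self, tiny_model):
        import copy
        m = copy.deepcopy(tiny_model)
        for i, head in enumerate(m.heads):
            head.weight.data[:] = 0
            head.bias.data[:] = 0.5 + i
        pmap = m(RNG.normal(0, 1, (3, 64, 64)).astype(np.float32))
        np.testing.assert_allclose(pmap.logits, 0.5 + 1.5 + 2.5 + 3.5, atol=1e-5)

    def test_head_param_count_default(self):
        cfg = ModelConfig()
        model = TCDNet(cfg, rng=0)
        assert sum(h.n_params() for h in model.heads) == 4 * (256 + 1) == 1028

    def test_deterministic_forward(self, tiny_model):
        x = RNG.normal(0, 1, (3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(tiny_model(x).logits, tiny_model(x).logits)

    def test_indivisible_input_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model(RNG.normal(0, 1, (3, 60, 60)).astype(np.float32))
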