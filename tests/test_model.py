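"""Network architecture: blocks, shape algebra, parameter bookkeeping."""
import numpy as np
import pytest

from mgaca.ablation import ABLATION_NAMES, ablation_variant
from mgaca.config import ModelConfig
from mgaca.model import (ASPPBlock, AttentionBlock, MGACANet, build_mgaca,
                         count_trainable_parameters, se_block)
from mgaca.nn import autodiff as ad
from mgaca.nn.layers import Conv2D, ConvBNReLU, SqueezeExcite

SMALL = dict(width_multiplier=0.125, input_shape=(32, 32, 3))


class TestSqueezeExcite:
    def test_parameter_count_is_two_bottleneck_maps(self, rng):
        # two bias-free dense maps: C*(C/r) + (C/r)*C = 2*C^2/r
        block = SqueezeExcite(256, rng, ratio=8)
        assert block.count_parameters() == 16384
        assert SqueezeExcite(64, rng, ratio=16).count_parameters() == \
            2 * 64 * 64 // 16

    def test_shape_preserved_and_gates_shrink(self, rng):
        x = rng.random((2, 5, 7, 16)).astype(np.float32)
        y = se_block(x, ratio=8, seed=1)
        assert y.shape == x.shape
        assert (np.abs(y) <= np.abs(x) + 1e-6).all()

    def test_ratio_must_divide_channels(self, rng):
        with pytest.raises(ValueError, match="ratio"):
            SqueezeExcite(100, rng, ratio=8)


class TestAttentionBlock:
    def test_spatial_shape_preserved(self, rng):
        conv = ConvBNReLU(8, 16, 3, rng, dilation=6)
        att = AttentionBlock(16, 8, rng)
        x = ad.constant(rng.random((1, 20, 20, 8)).astype(np.float32))
        out = att(conv(x), x)
        assert out.shape == (1, 20, 20, 16)

    def test_attention_weights_in_unit_interval(self, rng):
        att = AttentionBlock(8, 8, rng)
        feats = ad.constant(rng.normal(size=(1, 6, 6, 8)).astype(np.float32))
        w = att.attention_weights(feats).data
        assert (w > 0).all() and (w < 1).all()

    def test_zero_input_zero_bias_gives_zero_preactivation(self, rng):
        conv = Conv2D(4, 8, 3, rng, dilation=6, use_bias=True)
        conv.bias.data[:] = 0.0
        out = conv(ad.constant(np.zeros((1, 8, 8, 4), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)


class TestASPP:
    def test_concat_width_from_branch_filters(self, rng):
        cfg = ModelConfig()
        # attended branches only: pool + 1x1 + att6 + att18
        lean = ASPPBlock(256, cfg.replace(aspp_include_raw=(False, False)), rng)
        assert lean.concat_channels == 256 + 256 + 256 + 1024
        # published default also carries the raw dilation-18 tensor
        full = ASPPBlock(256, cfg, rng)
        assert full.concat_channels == 256 + 256 + 256 + 1024 + 1024

    def test_output_spatial_size_matches_input(self, rng):
        cfg = ModelConfig(**SMALL)
        block = ASPPBlock(32, cfg, rng)
        x = rng.random((1, 4, 4, 32)).astype(np.float32)
        out = block(ad.constant(x))
        assert out.shape[:3] == (1, 4, 4)


class TestBuildMgaca:
    def test_forward_contract_on_zero_batch(self):
        net = build_mgaca(**SMALL)
        y = net.forward(np.zeros((2, 32, 32, 3), dtype=np.float32))
        assert y.shape == (2, 32, 32, 1)
        assert np.isfinite(y.data).all()
        assert (y.data > 0).all() and (y.data < 1).all()

    def test_output_strictly_inside_unit_interval(self, rng):
        net = build_mgaca(**SMALL)
        y = net.forward(rng.random((2, 32, 32, 3)).astype(np.float32))
        assert (y.data > 0).all() and (y.data < 1).all()

    @pytest.mark.parametrize("wm", [0.125, 0.25, 0.5])
    def test_shape_algebra_across_width_grid(self, wm):
        net = build_mgaca(width_multiplier=wm, input_shape=(32, 32, 3))
        y = net.forward(np.zeros((1, 32, 32, 3), dtype=np.float32))
        assert y.shape == (1, 32, 32, 1)

    def test_width_multiplier_monotonicity(self):
        n_full = count_trainable_parameters(build_mgaca())
        n_quarter = count_trainable_parameters(build_mgaca(width_multiplier=0.25))
        assert n_quarter < n_full

    def test_count_invariant_to_forward_and_batch_size(self):
        net = build_mgaca(**SMALL)
        n0 = count_trainable_parameters(net)
        net.forward(np.zeros((1, 32, 32, 3), dtype=np.float32), training=True)
        net.forward(np.zeros((3, 32, 32, 3), dtype=np.float32), training=False)
        assert count_trainable_parameters(net) == n0

    def test_verbose_count_includes_bn_statistics(self):
        net = build_mgaca(**SMALL)
        tallies = count_trainable_parameters(net, verbose=True)
        assert tallies["with_batchnorm_statistics"] > tallies["trainable"]

    def test_softmax_head_mode_contract(self, rng):
        net = build_mgaca(output_activation="softmax2", **SMALL)
        y = net.forward(rng.random((1, 32, 32, 3)).astype(np.float32))
        assert y.shape == (1, 32, 32, 1)
        assert (y.data > 0).all() and (y.data < 1).all()

    def test_pretrained_request_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="pretrained"):
            build_mgaca(pretrained_encoder=True, **SMALL)

    def test_input_must_match_encoder_stride(self):
        with pytest.raises(ValueError, match="divisible"):
            build_mgaca(width_multiplier=0.125, input_shape=(30, 30, 3))

    def test_dilation_rates_must_increase(self):
        with pytest.raises(ValueError, match="dilation"):
            ModelConfig(dilation_rates=(18, 6))

    def test_layer_registry_names_blocks(self):
        net = build_mgaca(**SMALL)
        names = set(net.layers)
        assert {"encoder", "aspp", "lowlevel_proj", "decoder_conv1",
                "decoder_conv2", "head"} <= names

    def test_aspp_subgraph_accounts_for_removal_difference(self, rng):
        cfg = ModelConfig()
        full = count_trainable_parameters(build_mgaca(cfg))
        without = count_trainable_parameters(ablation_variant("no_aspp", cfg))
        aspp = ASPPBlock(256, cfg, np.random.default_rng(0)).count_parameters()
        replacement = ConvBNReLU(256, 256, 1, np.random.default_rng(0),
                                 use_bias=True).count_parameters()
        assert full - without == aspp - replacement


class TestAblations:
    def test_seven_named_variants(self):
        assert len(ABLATION_NAMES) == 7

    def test_unknown_variant_lists_choices(self):
        with pytest.raises(ValueError, match="no_aspp"):
            ablation_variant("bogus")

    @pytest.mark.parametrize("name", ABLATION_NAMES)
    def test_variant_forward_contract_reduced_width(self, name, rng):
        cfg = ModelConfig(**SMALL)
        net = ablation_variant(name, cfg)
        y = net.forward(rng.random((1, 32, 32, 3)).astype(np.float32))
        assert y.shape == (1, 32, 32, 1)
        assert (y.data > 0).all() and (y.data < 1).all()
        assert count_trainable_parameters(net) < \
            count_trainable_parameters(build_mgaca(cfg))
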