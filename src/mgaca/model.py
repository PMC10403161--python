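"""The MGACA localization network.

Multi-scale guided-attention context aggregation: a VGG19-style convolutional
encoder feeds an atrous spatial pyramid pooling (ASPP) head whose dilated
branches carry guided-attention gating, squeeze-and-excite (SE) blocks
recalibrate channels throughout, and a decoder fuses a 1x1-projected copy of
the feature-map layer before a spatial attention gate and a single-channel
localization head.
"""
from __future__ import annotations

import warnings

import numpy as np

from .config import ModelConfig
from .nn import autodiff as ad
from .nn.layers import (BatchNorm2D, Conv2D, ConvBNReLU, Module,
                        SqueezeExcite)

# VGG19 convolutional stage widths and conv counts (fully-connected top removed)
VGG19_WIDTHS = (64, 128, 256, 512, 512)
VGG19_DEPTHS = (2, 2, 4, 4, 4)


def _tap_index(name: str) -> int:
    if not (name.startswith("block") and name.endswith("_pool")):
        raise ValueError(f"unknown encoder tap {name!r}; expected 'block<i>_pool'")
    i = int(name[len("block"):-len("_pool")])
    if not 1 <= i <= len(VGG19_WIDTHS):
        raise ValueError(f"encoder tap stage {i} out of range 1..{len(VGG19_WIDTHS)}")
    return i


class VGG19Encoder(Module):
    """Stacked 3x3 conv stages with 2x2 max pooling, VGG19 layout."""

    def __init__(self, config: ModelConfig, rng, n_blocks: int):
        self.n_blocks = n_blocks
        self.blocks = []
        cin = config.input_shape[2]
        for b in range(n_blocks):
            cout = config.scaled(VGG19_WIDTHS[b])
            convs = []
            for _ in range(VGG19_DEPTHS[b]):
                convs.append(Conv2D(cin, cout, 3, rng, use_bias=True))
                cin = cout
            self.blocks.append(_ConvStack(convs))
        self.out_channels = cin

    def __call__(self, x, training=False):
        taps = {}
        for b, block in enumerate(self.blocks, start=1):
            x = block(x, training=training)
            x = ad.maxpool2(x)
            taps[f"block{b}_pool"] = x
        return taps


class _ConvStack(Module):
    def __init__(self, convs):
        self.convs = convs

    def __call__(self, x, training=False):
        for conv in self.convs:
            x = ad.relu(conv(x, training=training))
        return x


class AttentionBlock(Module):
    """Guided attention over a dilated-convolution branch.

    The incoming feature map is gated spatially and channel-wise by sigmoid
    weights from a 1x1 convolution, concatenated with the original (guide)
    features of the block's input, and fused by a 3x3 convolution with batch
    normalization and ReLU. With ``gating=False`` the sigmoid weighting is
    dropped and only the concatenate-and-fuse path remains.
    """

    def __init__(self, channels, guide_channels, rng, gating=True):
        self.gating = gating
        if gating:
            self.weight_conv = Conv2D(channels, channels, 1, rng, use_bias=True)
        self.fusion = ConvBNReLU(channels + guide_channels, channels, 3, rng,
                                 use_bias=True)

    def __call__(self, feats, guide, training=False):
        if self.gating:
            weights = ad.sigmoid(self.weight_conv(feats))
            feats = ad.mul(feats, weights)
        return self.fusion(ad.concat([feats, guide]), training=training)

    def attention_weights(self, feats):
        """The sigmoid attention map, for inspection; values lie in (0, 1)."""
        if not self.gating:
            raise ValueError("gating disabled: no attention weights")
        return ad.sigmoid(self.weight_conv(feats))


class ASPPBlock(Module):
    """Attention-augmented atrous spatial pyramid pooling.

    Branches: image-level pooling -> 1x1 conv -> upsample; a 1x1 convolution;
    and one dilated 3x3 convolution per dilation rate, each optionally
    followed by a guided-attention block. The branch outputs (attended
    versions, plus the raw dilated tensors flagged in the config) are
    concatenated on channels and fused by a 1x1 convolution.
    """

    def __init__(self, in_channels, config: ModelConfig, rng):
        c = config
        self.config = c
        self.pool_conv = Conv2D(in_channels, c.scaled(c.aspp_filters_pool), 1,
                                rng, use_bias=True)
        self.conv_1x1 = ConvBNReLU(in_channels, c.scaled(c.aspp_filters_1x1),
                                   1, rng, use_bias=True)
        branch_filters = (c.aspp_filters_d6, c.aspp_filters_d18)
        self.dilated = []
        self.attentions = []
        concat_ch = c.scaled(c.aspp_filters_pool) + c.scaled(c.aspp_filters_1x1)
        attended = c.attended_rates
        for rate, nf, raw in zip(c.dilation_rates, branch_filters,
                                 c.aspp_include_raw):
            nf = c.scaled(nf)
            self.dilated.append(ConvBNReLU(in_channels, nf, 3, rng,
                                           dilation=rate, use_bias=True))
            if rate in attended:
                self.attentions.append(AttentionBlock(nf, in_channels, rng,
                                                      gating=c.attention_gating))
                concat_ch += nf
            else:
                self.attentions.append(None)
                raw = True  # an unattended branch contributes its raw tensor
            if raw:
                concat_ch += nf
            self._raw_flags = getattr(self, "_raw_flags", []) + [raw]
        self.out_channels = c.scaled(c.aspp_out_filters)
        self.project = Conv2D(concat_ch, self.out_channels, 1, rng, use_bias=True)
        self.concat_channels = concat_ch

    def __call__(self, x, training=False):
        h, w = x.shape[1], x.shape[2]
        pooled = ad.global_avg_pool(x)
        pooled = ad.relu(self.pool_conv(pooled))
        pools = [ad.resize(pooled, (h, w), method="bilinear")]
        pools.append(self.conv_1x1(x, training=training))
        for conv, att, raw in zip(self.dilated, self.attentions, self._raw_flags):
            feats = conv(x, training=training)
            if raw:
                pools.append(feats)
            if att is not None:
                pools.append(att(feats, x, training=training))
        return ad.relu(self.project(ad.concat(pools)))


class MGACANet(Module):
    """The full network; forward maps (N,H,W,3) in [0,1] to (N,H,W,1) in (0,1)."""

    def __init__(self, config: ModelConfig):
        c = config
        self.config = c
        if c.pretrained_encoder:
            warnings.warn("pretrained encoder weights are not available; "
                          "falling back to He-normal random initialization")
        rng = np.random.default_rng(c.seed)
        self._dropout_rng = np.random.default_rng((c.seed + 1) & 0x7FFFFFFF)

        self._feat_stage = _tap_index(c.feature_tap)
        self._low_stage = _tap_index(c.lowlevel_tap)
        h, w, _ = c.input_shape
        stride = 2 ** max(self._feat_stage, self._low_stage)
        if h % stride or w % stride:
            raise ValueError(f"input size {h}x{w} must be divisible by the "
                             f"encoder stride {stride}")
        self.encoder = VGG19Encoder(c, rng, max(self._feat_stage, self._low_stage))
        feat_ch = c.scaled(VGG19_WIDTHS[self._feat_stage - 1])
        low_ch = c.scaled(VGG19_WIDTHS[self._low_stage - 1])

        if c.use_aspp:
            self.aspp = ASPPBlock(feat_ch, c, rng)
            ctx_ch = self.aspp.out_channels
        else:
            self.aspp = ConvBNReLU(feat_ch, c.scaled(c.aspp_out_filters), 1,
                                   rng, use_bias=True)
            ctx_ch = c.scaled(c.aspp_out_filters)

        if c.use_se:
            self.se_context = SqueezeExcite(ctx_ch, rng, ratio=c.se_ratio)
        self.lowlevel_proj = ConvBNReLU(low_ch, c.scaled(c.lowlevel_filters), 1,
                                        rng, use_bias=False)
        cat_ch = ctx_ch + c.scaled(c.lowlevel_filters)
        if c.use_se:
            self.se_fused = SqueezeExcite(cat_ch, rng, ratio=c.se_ratio)
        d1, d2 = (c.scaled(f) for f in c.decoder_filters)
        self.decoder_conv1 = ConvBNReLU(cat_ch, d1, 3, rng, use_bias=False)
        self.decoder_conv2 = ConvBNReLU(d1, d2, 3, rng, use_bias=False)
        if c.use_se:
            self.se_decoder = SqueezeExcite(d2, rng, ratio=c.se_ratio)
        if c.use_spatial_gate:
            self.spatial_gate = Conv2D(d2, 1, 1, rng, use_bias=True)
        out_ch = 2 if c.output_activation == "softmax2" else 1
        self.head = Conv2D(d2, out_ch, 1, rng, use_bias=True)

    # -- forward ------------------------------------------------------------
    def forward(self, x, training=False):
        c = self.config
        if not isinstance(x, ad.Var):
            x = ad.constant(np.asarray(x, dtype=np.float32))
        if x.data.ndim != 4 or x.data.shape[3] != 3:
            raise ValueError(f"expected (N, H, W, 3) input, got {x.data.shape}")
        taps = self.encoder(x, training=training)
        feats = taps[c.feature_tap]
        low = taps[c.lowlevel_tap]

        y = self.aspp(feats, training=training)
        if c.use_se:
            y = self.se_context(y)
        if feats.shape[1:3] != low.shape[1:3]:
            y = ad.resize(y, low.shape[1:3], method="bilinear")
        low = self.lowlevel_proj(low, training=training)
        y = ad.concat([y, low])
        if c.use_se:
            y = self.se_fused(y)
        y = self.decoder_conv1(y, training=training)
        y = ad.dropout(y, c.dropout_rate, self._dropout_rng, training)
        y = self.decoder_conv2(y, training=training)
        y = ad.dropout(y, c.dropout_rate, self._dropout_rng, training)
        if c.use_se:
            y = self.se_decoder(y)
        if c.use_spatial_gate:
            y = ad.mul(y, ad.sigmoid(self.spatial_gate(y)))
        y = ad.resize(y, x.shape[1:3], method="bilinear")
        y = self.head(y)
        if c.output_activation == "softmax2":
            y = ad.channel_slice(ad.softmax_channels(y), 1, 2)
        else:
            y = ad.sigmoid(y)
        return y

    __call__ = forward

    def predict(self, x, batch_size=8):
        """Inference-mode probability maps as a numpy array."""
        x = np.asarray(x, dtype=np.float32)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i:i + batch_size], training=False).data)
        return np.concatenate(outs, axis=0)

    @property
    def layers(self):
        """Registry of named submodules."""
        registry = {}

        def walk(mod, prefix):
            for name, value in vars(mod).items():
                if isinstance(value, Module):
                    registry[f"{prefix}{name}"] = value
                    walk(value, f"{prefix}{name}.")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            registry[f"{prefix}{name}.{i}"] = item
                            walk(item, f"{prefix}{name}.{i}.")

        walk(self, "")
        return registry


def build_mgaca(config: ModelConfig | None = None, **overrides) -> MGACANet:
    """Instantiate the network; keyword overrides patch the default config."""
    if config is None:
        config = ModelConfig(**overrides)
    elif overrides:
        config = config.replace(**overrides)
    return MGACANet(config)


def count_trainable_parameters(net: Module, verbose: bool = False):
    """Total element count of the trainable weight arrays.

    Batch normalization contributes its scale and shift only; with
    ``verbose=True`` a second tally that also counts the (non-trainable)
    running statistics is reported alongside.
    """
    trainable = sum(p.size for p in net.parameters())
    if verbose:
        buffers = sum(b.size for _, b in net.named_buffers())
        return {"trainable": trainable,
                "with_batchnorm_statistics": trainable + buffers}
    return trainable


# -- functional wrappers over single blocks ---------------------------------

def se_block(features, ratio=8, seed=0):
    """Apply a freshly initialized squeeze-and-excite block to an array."""
    features = np.asarray(features, dtype=np.float32)
    rng = np.random.default_rng(seed)
    block = SqueezeExcite(features.shape[-1], rng, ratio=ratio)
    return block(ad.constant(features)).data


def attention_block(features, dilation, filters, seed=0, gating=True):
    """Dilated-conv guided attention applied to an array (random init)."""
    features = np.asarray(features, dtype=np.float32)
    rng = np.random.default_rng(seed)
    cin = features.shape[-1]
    conv = ConvBNReLU(cin, filters, 3, rng, dilation=dilation, use_bias=True)
    att = AttentionBlock(filters, cin, rng, gating=gating)
    x = ad.constant(features)
    return att(conv(x), x).data


def aspp_block(features, config: ModelConfig | None = None, seed=0):
    """Attention-augmented ASPP applied to an array (random init)."""
    features = np.asarray(features, dtype=np.float32)
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    block = ASPPBlock(features.shape[-1], config, rng)
    return block(ad.constant(features)).data
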