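"""Parameterized layers built on the autodiff engine.

Weight layout conventions follow Keras: convolution kernels are
(k, k, in_channels, out_channels), dense kernels (in, out), images NHWC.
Dense and convolution kernels use He-normal initialization.
"""
from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Var


class Module:
    """Base class: parameter discovery and state (de)serialization by name."""

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Var) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        """Non-trainable state (batch-norm running statistics)."""
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(value, np.ndarray):
                yield full, value

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                params[key].data[...] = value

    def count_parameters(self):
        return sum(p.size for p in self.parameters())


def _he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2D(Module):
    """Stride-1 "same"-padded (optionally dilated) 2-D convolution."""

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 dilation=1, use_bias=True):
        k = kernel_size
        self.weight = Var(_he_normal(rng, (k, k, in_channels, out_channels),
                                     k * k * in_channels), requires_grad=True)
        self.bias = (Var(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
                     if use_bias else None)
        self.dilation = dilation

    def __call__(self, x, training=False):
        return ad.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class Dense(Module):
    def __init__(self, in_features, out_features, rng, use_bias=True):
        self.weight = Var(_he_normal(rng, (in_features, out_features), in_features),
                          requires_grad=True)
        self.bias = (Var(np.zeros(out_features, dtype=np.float32), requires_grad=True)
                     if use_bias else None)

    def __call__(self, x, training=False):
        return ad.dense(x, self.weight, self.bias)


class BatchNorm2D(Module):
    """Per-channel batch normalization; running stats are non-trainable."""

    def __init__(self, channels, momentum=0.99, eps=1e-3):
        self.gamma = Var(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Var(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training=False):
        return ad.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, training,
                             momentum=self.momentum, eps=self.eps)


class ConvBNReLU(Module):
    """Conv -> BatchNorm -> ReLU, the standard unit in the network."""

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 dilation=1, use_bias=True):
        self.conv = Conv2D(in_channels, out_channels, kernel_size, rng,
                           dilation=dilation, use_bias=use_bias)
        self.bn = BatchNorm2D(out_channels)

    def __call__(self, x, training=False):
        return ad.relu(self.bn(self.conv(x), training=training))


class SqueezeExcite(Module):
    """Channel-recalibration block.

    Global average pooling produces one descriptor per channel; a bias-free
    two-layer bottleneck (ReLU then sigmoid, He-normal kernels) turns it into
    per-channel gates in (0, 1) that rescale the input feature maps.
    """

    def __init__(self, channels, rng, ratio=8):
        if channels % ratio:
            raise ValueError(
                f"SE ratio {ratio} must divide the channel count {channels}")
        self.squeeze = Dense(channels, channels // ratio, rng, use_bias=False)
        self.excite = Dense(channels // ratio, channels, rng, use_bias=False)

    def __call__(self, x, training=False):
        s = ad.global_avg_pool(x)
        gates = ad.sigmoid(self.excite(ad.relu(self.squeeze(s))))
        return ad.mul(x, gates)
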