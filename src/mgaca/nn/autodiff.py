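"""Reverse-mode automatic differentiation over numpy arrays.

A minimal dynamic-graph engine sized for the segmentation networks in this
package: stride-1 "same"-padded (dilated) 2-D convolutions, 2x2 max pooling,
batch normalization, dense maps, bilinear/nearest resampling, channel-wise
gating, and the elementwise/reduction ops the BCE+Dice training loss needs.
All tensors are float32 and images are laid out NHWC.
"""
from __future__ import annotations

import functools

import numpy as np


class Var:
    """A node in the computation graph: a value plus an optional backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate d(self)/d(leaf) into .grad of every reachable leaf."""
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar (scalars are promoted to constants) -----------------
    def __add__(self, other):
        return add(self, _as_var(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_var(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _as_var(-1.0))

    def __sub__(self, other):
        return add(self, -_as_var(other))

    def __rsub__(self, other):
        return add(_as_var(other), -self)

    def __truediv__(self, other):
        return div(self, _as_var(other))

    def __rtruediv__(self, other):
        return div(_as_var(other), self)

    def __repr__(self):
        return f"Var(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_var(x):
    return x if isinstance(x, Var) else Var(np.asarray(x, dtype=np.float32))


def constant(x):
    """Wrap an array as a non-differentiable graph leaf."""
    return _as_var(x)


def _unbroadcast(g, shape):
    """Reduce gradient g back to `shape` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a, b):
    out = Var(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b):
    out = Var(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def div(a, b):
    out = Var(a.data / b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    out._backward = backward
    return out


def relu(x):
    mask = x.data > 0
    out = Var(x.data * mask, parents=(x,))

    def backward(g):
        x.accumulate(g * mask)

    out._backward = backward
    return out


def sigmoid(x):
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Var(y, parents=(x,))

    def backward(g):
        x.accumulate(g * y * (1.0 - y))

    out._backward = backward
    return out


def log(x):
    out = Var(np.log(x.data), parents=(x,))

    def backward(g):
        x.accumulate(g / x.data)

    out._backward = backward
    return out


def clip(x, lo, hi):
    """Clamp values; gradient passes only through the unclipped region."""
    mask = (x.data > lo) & (x.data < hi)
    out = Var(np.clip(x.data, lo, hi), parents=(x,))

    def backward(g):
        x.accumulate(g * mask)

    out._backward = backward
    return out


def sum_all(x):
    out = Var(x.data.sum(), parents=(x,))

    def backward(g):
        x.accumulate(np.full_like(x.data, g))

    out._backward = backward
    return out


def mean_all(x):
    n = x.data.size
    out = Var(x.data.mean(), parents=(x,))

    def backward(g):
        x.accumulate(np.full_like(x.data, g / n))

    out._backward = backward
    return out


def concat(parts, axis=-1):
    out = Var(np.concatenate([p.data for p in parts], axis=axis), parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                p.accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def channel_slice(x, lo, hi):
    """Slice the trailing (channel) axis: x[..., lo:hi]."""
    out = Var(x.data[..., lo:hi], parents=(x,))

    def backward(g):
        full = np.zeros_like(x.data)
        full[..., lo:hi] = g
        x.accumulate(full)

    out._backward = backward
    return out


def softmax_channels(x):
    """Softmax over the trailing (channel) axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Var(y, parents=(x,))

    def backward(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        x.accumulate(y * (g - dot))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# dense / convolution
# ---------------------------------------------------------------------------

def dense(x, w, b=None):
    """Affine map over the trailing axis: x[..., cin] @ w[cin, cout] (+ b)."""
    y = x.data @ w.data
    if b is not None:
        y = y + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Var(y, parents=parents)

    def backward(g):
        if w.requires_grad:
            xf = x.data.reshape(-1, x.data.shape[-1])
            gf = g.reshape(-1, g.shape[-1])
            w.accumulate(xf.T @ gf)
        if b is not None and b.requires_grad:
            b.accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            x.accumulate(g @ w.data.T)

    out._backward = backward
    return out


def _im2col(x, k, dilation):
    """Gather kxk dilated patches of an NHWC array into (N, H, W, k*k*C)."""
    n, h, w, c = x.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            cols[..., idx * c:(idx + 1) * c] = xp[:, i * dilation:i * dilation + h,
                                                  j * dilation:j * dilation + w, :]
            idx += 1
    return cols


def _conv2d_raw(x, w, dilation):
    """Forward-only stride-1 same-padded convolution on raw arrays."""
    k = w.shape[0]
    cin, cout = w.shape[2], w.shape[3]
    if k == 1:
        return x @ w.reshape(cin, cout)
    cols = _im2col(x, k, dilation)
    n, h, wd = x.shape[:3]
    return (cols.reshape(-1, k * k * cin) @ w.reshape(-1, cout)).reshape(n, h, wd, cout)


def conv2d(x, w, b=None, dilation=1):
    """Stride-1 "same"-padded 2-D convolution (cross-correlation).

    x: (N, H, W, Cin); w: (k, k, Cin, Cout); optional bias (Cout,).
    """
    k = w.data.shape[0]
    cin, cout = w.data.shape[2], w.data.shape[3]
    if k == 1:
        wmat = w.data.reshape(cin, cout)
        y = x.data @ wmat
        if b is not None:
            y += b.data
        parents = (x, w) if b is None else (x, w, b)
        out = Var(y, parents=parents)

        def backward1(g):
            if w.requires_grad:
                xf = x.data.reshape(-1, cin)
                gf = g.reshape(-1, cout)
                w.accumulate((xf.T @ gf).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b.accumulate(g.reshape(-1, cout).sum(axis=0))
            if x.requires_grad:
                x.accumulate(g @ wmat.T)

        out._backward = backward1
        return out
    cols = _im2col(x.data, k, dilation) if (w.requires_grad or x.requires_grad) else None
    if cols is not None:
        n, h, wd = x.data.shape[:3]
        y = (cols.reshape(-1, k * k * cin) @ w.data.reshape(-1, cout)).reshape(n, h, wd, cout)
    else:
        y = _conv2d_raw(x.data, w.data, dilation)
    if b is not None:
        y += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Var(y, parents=parents)

    def backward(g):
        if w.requires_grad:
            gw = cols.reshape(-1, k * k * cin).T @ g.reshape(-1, cout)
            w.accumulate(gw.reshape(k, k, cin, cout))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            # input gradient = same-padded convolution of g with the
            # spatially flipped, channel-transposed kernel
            w_flip = w.data[::-1, ::-1].transpose(0, 1, 3, 2)
            x.accumulate(_conv2d_raw(g, np.ascontiguousarray(w_flip), dilation))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# pooling / resampling / normalization
# ---------------------------------------------------------------------------

def maxpool2(x):
    """2x2 max pooling, stride 2 (H and W must be even)."""
    n, h, w, c = x.data.shape
    xr = (x.data.reshape(n, h // 2, 2, w // 2, 2, c)
          .transpose(0, 1, 3, 5, 2, 4)
          .reshape(n, h // 2, w // 2, c, 4))
    arg = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    out = Var(y, parents=(x,))

    def backward(g):
        gz = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(gz, arg[..., None], g[..., None], axis=-1)
        gx = (gz.reshape(n, h // 2, w // 2, c, 2, 2)
              .transpose(0, 1, 4, 2, 5, 3)
              .reshape(n, h, w, c))
        x.accumulate(gx)

    out._backward = backward
    return out


def global_avg_pool(x):
    """Spatial mean, keeping singleton H and W axes: (N,H,W,C) -> (N,1,1,C)."""
    n, h, w, c = x.data.shape
    out = Var(x.data.mean(axis=(1, 2), keepdims=True), parents=(x,))

    def backward(g):
        x.accumulate(np.broadcast_to(g / (h * w), x.data.shape))

    out._backward = backward
    return out


@functools.lru_cache(maxsize=64)
def _resample_matrix(n_in, n_out, method):
    """1-D resampling operator (n_out x n_in), half-pixel-centered."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        if method == "nearest":
            m[o, int(np.clip(round(src), 0, n_in - 1))] = 1.0
        else:
            i0 = int(np.floor(src))
            frac = src - i0
            i0c = int(np.clip(i0, 0, n_in - 1))
            i1c = int(np.clip(i0 + 1, 0, n_in - 1))
            m[o, i0c] += 1.0 - frac
            m[o, i1c] += frac
    return m


def resize(x, out_hw, method="bilinear"):
    """Resample an NHWC tensor to (out_h, out_w)."""
    n, h, w, c = x.data.shape
    oh, ow = out_hw
    a = _resample_matrix(h, oh, method)
    b = _resample_matrix(w, ow, method)
    y = np.einsum("oi,nijc->nojc", a, x.data)
    y = np.einsum("pj,nojc->nopc", b, y)
    out = Var(y, parents=(x,))

    def backward(g):
        t = np.einsum("oi,nopc->nipc", a, g)
        x.accumulate(np.einsum("pj,nipc->nijc", b, t))

    out._backward = backward
    return out


def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.99, eps=1e-3):
    """Batch normalization over (N, H, W) per channel.

    `running_mean`/`running_var` are plain numpy arrays mutated in place when
    training; gamma/beta are the trainable scale and shift.
    """
    if training:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = Var(gamma.data * xhat + beta.data, parents=(x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            if training:
                m = x.data.size // x.data.shape[-1]
                gxh = g * gamma.data
                gx = (inv_std / m) * (m * gxh
                                      - gxh.sum(axis=(0, 1, 2))
                                      - xhat * (gxh * xhat).sum(axis=(0, 1, 2)))
            else:
                gx = g * gamma.data * inv_std
            x.accumulate(gx)

    out._backward = backward
    return out


def dropout(x, rate, rng, training):
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    out = Var(x.data * mask, parents=(x,))

    def backward(g):
        x.accumulate(g * mask)

    out._backward = backward
    return out
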