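"""Layers with explicit forward/backward.

Convolutions are im2col matmuls; the input gradient is computed by
multiplying the output gradient back through the kernel matrix and
scatter-adding the resulting column gradients to their input positions
(col2im).  Caches are only kept in training mode.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import DTYPE, Module, Param


def _tup(v, d):
    return tuple(v) if isinstance(v, (tuple, list)) else (v,) * d


def _pad_spatial(x, padding, value=0.0):
    if all(p == 0 for p in padding):
        return x
    pad = [(0, 0), (0, 0)] + [(p, p) for p in padding]
    return np.pad(x, pad, mode="constant", constant_values=value)


def _windows(x, kernel, stride):
    """(N, C, *S) -> strided view (N, C, *Out, *K)."""
    d = len(kernel)
    win = sliding_window_view(x, kernel, axis=tuple(range(2, 2 + d)))
    sl = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)
    return win[sl]


def _im2col(x, kernel, stride, groups):
    """Return cols (N, L, G, Cg*K) and the spatial output shape."""
    n, c = x.shape[:2]
    d = len(kernel)
    win = _windows(x, kernel, stride)
    out_shape = win.shape[2 : 2 + d]
    order = (0,) + tuple(range(2, 2 + d)) + (1,) + tuple(range(2 + d, 2 + 2 * d))
    cols = win.transpose(order).reshape(
        n, int(np.prod(out_shape)), groups, (c // groups) * int(np.prod(kernel))
    )
    return np.ascontiguousarray(cols), out_shape


def _gemm(cols, wg):
    """cols (N, L, G, K) x wg (G, Fg, K) -> (N, L, G, Fg) via BLAS matmul."""
    n, l, g, k = cols.shape
    if g == 1:
        out = cols.reshape(n * l, k) @ wg[0].T
        return out.reshape(n, l, 1, -1)
    cg = np.ascontiguousarray(cols.transpose(2, 0, 1, 3).reshape(g, n * l, k))
    out = np.matmul(cg, wg.transpose(0, 2, 1))        # (G, N*L, Fg)
    return np.ascontiguousarray(out.transpose(1, 0, 2)).reshape(n, l, g, -1)


def _gemm_weight_grad(gg, cols):
    """gg (N, L, G, Fg) x cols (N, L, G, K) -> (G, Fg, K)."""
    n, l, g, fg = gg.shape
    k = cols.shape[-1]
    if g == 1:
        return (gg.reshape(n * l, fg).T @ cols.reshape(n * l, k))[None]
    a = np.ascontiguousarray(gg.transpose(2, 3, 0, 1).reshape(g, fg, n * l))
    b = np.ascontiguousarray(cols.transpose(2, 0, 1, 3).reshape(g, n * l, k))
    return np.matmul(a, b)


def _corr(x, w, stride, padding, groups):
    """Grouped correlation.  x (N,C,*S); w (F, C//G, *K) -> (N, F, *Out)."""
    kernel = w.shape[2:]
    xp = _pad_spatial(x, padding)
    cols, out_shape = _im2col(xp, kernel, stride, groups)
    f = w.shape[0]
    wg = w.reshape(groups, f // groups, -1)
    out = _gemm(cols, wg)
    n = x.shape[0]
    out = out.reshape(n, -1, f).transpose(0, 2, 1).reshape(n, f, *out_shape)
    return np.ascontiguousarray(out), cols, out_shape


class Conv(Module):
    """N-dimensional (2 or 3 spatial axes) grouped convolution."""

    def __init__(self, in_channels, out_channels, kernel_size, *, ndim,
                 stride=1, padding=0, groups=1, bias=True, rng=None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.ndim = ndim
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _tup(kernel_size, ndim)
        self.stride = _tup(stride, ndim)
        self.padding = _tup(padding, ndim)
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * int(np.prod(self.kernel))
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std,
                                       (out_channels, in_channels // groups, *self.kernel)))
        self.bias = Param(np.zeros(out_channels)) if bias else None
        # set for the first layer of an encoder, where the input is raw data
        # and its gradient is never consumed
        self.skip_input_grad = False
        self._cache = None

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        out, cols, out_shape = _corr(x, self.weight.data, self.stride,
                                     self.padding, self.groups)
        if self.bias is not None:
            out += self.bias.data.reshape(1, -1, *([1] * self.ndim))
        if self.training:
            self._cache = (cols, x.shape, out_shape)
        return out

    def backward(self, grad):
        cols, x_shape, out_shape = self._cache
        n, f = grad.shape[:2]
        g = grad.reshape(n, f, -1).transpose(0, 2, 1)  # (N, L, F)
        fg = f // self.groups
        gg = g.reshape(n, -1, self.groups, fg)
        gw = _gemm_weight_grad(gg, cols)
        self.weight.grad += gw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0,) + tuple(range(2, 2 + self.ndim)))
        if self.skip_input_grad:
            return None
        return self._input_grad(grad, x_shape, out_shape)

    def _input_grad(self, grad, x_shape, out_shape):
        k, s, p = self.kernel, self.stride, self.padding
        n = grad.shape[0]
        c = self.in_channels
        g = grad.reshape(n, self.out_channels, -1).transpose(0, 2, 1)
        fg = self.out_channels // self.groups
        gg = np.ascontiguousarray(g).reshape(n, -1, self.groups, fg)
        wg = self.weight.data.reshape(self.groups, fg, -1)   # (G, Fg, Cg*K)
        l = gg.shape[1]
        if self.groups == 1:
            gcol = (gg.reshape(n * l, fg) @ wg[0]).reshape(n, l, 1, -1)
        else:
            a = np.ascontiguousarray(
                gg.transpose(2, 0, 1, 3).reshape(self.groups, n * l, fg))
            gcol = np.matmul(a, wg)                          # (G, N*L, Cg*K)
            gcol = np.ascontiguousarray(gcol.transpose(1, 0, 2)).reshape(
                n, l, self.groups, -1)
        # (N, *Out, C, *K) -> (N, C, *Out, *K), then scatter each kernel
        # offset back onto the padded-input gradient (col2im)
        blk = gcol.reshape(n, *out_shape, c, *k)
        order = (0, 1 + self.ndim) + tuple(range(1, 1 + self.ndim)) + tuple(
            range(2 + self.ndim, 2 + 2 * self.ndim))
        blk = blk.transpose(order)
        m = tuple(si + 2 * pi for si, pi in zip(x_shape[2:], p))
        gxp = np.zeros((n, c, *m), dtype=DTYPE)
        for kk in np.ndindex(*k):
            sl = tuple(slice(kki, kki + st * o, st)
                       for kki, st, o in zip(kk, s, out_shape))
            gxp[(slice(None), slice(None)) + sl] += blk[(Ellipsis,) + kk]
        if all(pi == 0 for pi in p):
            return gxp
        crop = (slice(None), slice(None)) + tuple(
            slice(pi, pi + si) for pi, si in zip(p, x_shape[2:]))
        return np.ascontiguousarray(gxp[crop])


def Conv2d(*a, **k):
    return Conv(*a, ndim=2, **k)


def Conv3d(*a, **k):
    return Conv(*a, ndim=3, **k)


class BatchNorm(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(channels, dtype=DTYPE))
        self._cache = None

    def _cshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x):
        axes = (0,) + tuple(range(2, x.ndim))
        cs = self._cshape(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mean.astype(DTYPE)
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var.astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(cs)) * invstd.reshape(cs)
        if self.training:
            self._cache = (xhat, invstd, axes, cs)
        return (self.gamma.data.reshape(cs) * xhat + self.beta.data.reshape(cs)).astype(DTYPE)

    def backward(self, grad):
        xhat, invstd, axes, cs = self._cache
        m = grad.size // grad.shape[1]
        self.beta.grad += grad.sum(axis=axes)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        gsum = grad.sum(axis=axes).reshape(cs)
        gx_sum = (grad * xhat).sum(axis=axes).reshape(cs)
        coef = (self.gamma.data.reshape(cs) * invstd.reshape(cs)) / m
        return (coef * (m * grad - gsum - xhat * gx_sum)).astype(DTYPE)


class ReLU(Module):
    def forward(self, x):
        if self.training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class SiLU(Module):
    def forward(self, x):
        s = 1.0 / (1.0 + np.exp(-x))
        if self.training:
            self._cache = (x, s)
        return x * s

    def backward(self, grad):
        x, s = self._cache
        return grad * (s * (1.0 + x * (1.0 - s)))


class Sigmoid(Module):
    def forward(self, x):
        out = 1.0 / (1.0 + np.exp(-x))
        if self.training:
            self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, (out_features, in_features)))
        self.bias = Param(np.zeros(out_features)) if bias else None

    def forward(self, x):
        if self.training:
            self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out.astype(DTYPE)

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return (grad @ self.weight.data).astype(DTYPE)


class _Pool(Module):
    def __init__(self, kernel_size, stride=None, padding=0, *, ndim):
        super().__init__()
        self.ndim = ndim
        self.kernel = _tup(kernel_size, ndim)
        self.stride = _tup(stride if stride is not None else kernel_size, ndim)
        self.padding = _tup(padding, ndim)

    def _geometry(self, x_shape, out_shape):
        m = tuple(s + 2 * p for s, p in zip(x_shape[2:], self.padding))
        mstrides = np.array([int(np.prod(m[i + 1:])) for i in range(self.ndim)])
        starts = [np.arange(o) * st for o, st in zip(out_shape, self.stride)]
        start_flat = sum(np.ix_(*(s * ms for s, ms in zip(starts, mstrides))))
        offs = np.array(list(np.ndindex(*self.kernel)))
        off_flat = offs @ mstrides
        return m, start_flat.ravel(), off_flat


class MaxPool(_Pool):
    def forward(self, x):
        xp = _pad_spatial(x, self.padding, value=-np.inf)
        win = _windows(xp, self.kernel, self.stride)
        out_shape = win.shape[2 : 2 + self.ndim]
        n, c = x.shape[:2]
        flat = win.reshape(n, c, *out_shape, -1).reshape(n, c, -1, int(np.prod(self.kernel)))
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if self.training:
            self._cache = (arg, x.shape, out_shape)
        return np.ascontiguousarray(out.reshape(n, c, *out_shape))

    def backward(self, grad):
        arg, x_shape, out_shape = self._cache
        n, c = x_shape[:2]
        m, start_flat, off_flat = self._geometry(x_shape, out_shape)
        idx = start_flat[None, None, :] + off_flat[arg]
        gflat = np.zeros((n, c, int(np.prod(m))), dtype=DTYPE)
        ni, ci = np.ix_(np.arange(n), np.arange(c), np.arange(idx.shape[-1]))[:2]
        np.add.at(gflat, (ni, ci, idx), grad.reshape(n, c, -1))
        gxp = gflat.reshape(n, c, *m)
        crop = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for p, s in zip(self.padding, x_shape[2:]))
        return np.ascontiguousarray(gxp[crop])


class AvgPool(_Pool):
    def forward(self, x):
        xp = _pad_spatial(x, self.padding)
        win = _windows(xp, self.kernel, self.stride)
        out_shape = win.shape[2 : 2 + self.ndim]
        out = win.mean(axis=tuple(range(2 + self.ndim, 2 + 2 * self.ndim)))
        if self.training:
            self._cache = (x.shape, out_shape)
        return np.ascontiguousarray(out.astype(DTYPE))

    def backward(self, grad):
        x_shape, out_shape = self._cache
        n, c = x_shape[:2]
        k = int(np.prod(self.kernel))
        m, start_flat, off_flat = self._geometry(x_shape, out_shape)
        gflat = np.zeros((n, c, int(np.prod(m))), dtype=DTYPE)
        g = grad.reshape(n, c, -1) / k
        ni, ci = np.ix_(np.arange(n), np.arange(c), np.arange(g.shape[-1]))[:2]
        for off in off_flat:
            np.add.at(gflat, (ni, ci, start_flat[None, None, :] + off), g)
        gxp = gflat.reshape(n, c, *m)
        crop = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for p, s in zip(self.padding, x_shape[2:]))
        return np.ascontiguousarray(gxp[crop])


def MaxPool2d(*a, **k):
    return MaxPool(*a, ndim=2, **k)


def MaxPool3d(*a, **k):
    return MaxPool(*a, ndim=3, **k)


class GlobalPool(Module):
    """Global max (GMP) or average (GAP) pooling: (N, C, *S) -> (N, C)."""

    def __init__(self, mode: str):
        super().__init__()
        if mode not in ("max", "avg"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.mode = mode

    def forward(self, x):
        if x.ndim < 3 or int(np.prod(x.shape[2:])) == 0:
            raise ValueError("global pooling needs at least one spatial position")
        n, c = x.shape[:2]
        flat = x.reshape(n, c, -1)
        if self.mode == "max":
            arg = flat.argmax(axis=-1)
            out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
            if self.training:
                self._cache = (arg, x.shape)
        else:
            out = flat.mean(axis=-1)
            if self.training:
                self._cache = (None, x.shape)
        return np.ascontiguousarray(out.astype(DTYPE))

    def backward(self, grad):
        arg, x_shape = self._cache
        n, c = x_shape[:2]
        l = int(np.prod(x_shape[2:]))
        if self.mode == "max":
            gflat = np.zeros((n, c, l), dtype=DTYPE)
            np.put_along_axis(gflat, arg[..., None], grad[..., None].astype(DTYPE), axis=-1)
        else:
            gflat = np.broadcast_to((grad / l)[..., None], (n, c, l)).astype(DTYPE)
        return gflat.reshape(x_shape).copy()


class SEBlock(Module):
    """Squeeze-excitation: channel-wise gating from globally pooled features."""

    def __init__(self, channels, reduction=4, rng=None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.act = SiLU()
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.gate = Sigmoid()

    def forward(self, x):
        n, c = x.shape[:2]
        z = x.reshape(n, c, -1).mean(axis=-1)
        s = self.gate(self.fc2(self.act(self.fc1(z))))
        cs = (n, c) + (1,) * (x.ndim - 2)
        if self.training:
            self._cache = (x, s, cs)
        return (x * s.reshape(cs)).astype(DTYPE)

    def backward(self, grad):
        x, s, cs = self._cache
        n, c = x.shape[:2]
        l = int(np.prod(x.shape[2:]))
        gx = (grad * s.reshape(cs)).astype(DTYPE)
        gs = (grad * x).reshape(n, c, -1).sum(axis=-1).astype(DTYPE)
        gz = self.fc1.backward(self.act.backward(self.fc2.backward(self.gate.backward(gs))))
        gx += (gz / l).reshape(cs)
        return gx
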