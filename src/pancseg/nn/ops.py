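"""Differentiable array operations for 2D segmentation networks.

Reverse-mode differentiation is delegated to ``autograd``; the operations
here that autograd's numpy wrapper does not cover efficiently (stride-1
convolution, 2x stride-2 transposed convolution, 2x2 max pooling, bilinear
resampling) are registered as primitives with hand-written vector-Jacobian
products.  All tensors are NCHW ``float64`` arrays; batch size is 1
throughout the package but the ops are written for general N.
"""

from __future__ import annotations

from functools import lru_cache

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.tracer import getval  # noqa: F401  (re-exported)
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "resize_bilinear",
    "resize_nearest",
    "stop_gradient",
    "sigmoid",
    "relu",
    "softmax",
    "batchnorm",
    "getval",
]


def _windows(xp: np.ndarray, kh: int, kw: int, dilation: int) -> np.ndarray:
    """Sliding view (N, C, Ho, Wo, kh, kw) with dilated taps."""
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))
    if dilation > 1:
        win = win[..., ::dilation, ::dilation]
    return win


@primitive
def conv2d(x, w, b, padding=0, dilation=1):
    """Stride-1 cross-correlation. x:(N,C,H,W) w:(O,C,kh,kw) b:(O,)."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _windows(x, w.shape[2], w.shape[3], dilation)
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)
    return out + b[None, :, None, None]


def _conv2d_vjp_x(ans, x, w, b, padding=0, dilation=1):
    kh, kw = w.shape[2], w.shape[3]
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1

    def vjp(g):
        gp = np.pad(
            g,
            ((0, 0), (0, 0), (eh - 1 - padding,) * 2, (ew - 1 - padding,) * 2),
        )
        win = _windows(gp, kh, kw, dilation)
        wf = w[:, :, ::-1, ::-1]
        return np.tensordot(win, wf, axes=([1, 4, 5], [0, 2, 3])).transpose(0, 3, 1, 2)

    return vjp


def _conv2d_vjp_w(ans, x, w, b, padding=0, dilation=1):
    def vjp(g):
        xp = x
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
        win = _windows(xp, w.shape[2], w.shape[3], dilation)
        return np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))

    return vjp


defvjp(
    conv2d,
    _conv2d_vjp_x,
    _conv2d_vjp_w,
    lambda ans, x, w, b, padding=0, dilation=1: lambda g: g.sum((0, 2, 3)),
)


@primitive
def conv_transpose2x2(x, w, b):
    """Transposed convolution, kernel 2, stride 2. x:(N,C,H,W) w:(C,O,2,2)."""
    n, c, h, wd = x.shape
    o = w.shape[1]
    out = np.einsum("nchw,codq->nohdwq", x, w, optimize=True)
    out = out.reshape(n, o, 2 * h, 2 * wd)
    return out + b[None, :, None, None]


def _ct_vjp_x(ans, x, w, b):
    def vjp(g):
        n, o, h2, w2 = g.shape
        gr = g.reshape(n, o, h2 // 2, 2, w2 // 2, 2)
        return np.einsum("nohdwq,codq->nchw", gr, w, optimize=True)

    return vjp


def _ct_vjp_w(ans, x, w, b):
    def vjp(g):
        n, o, h2, w2 = g.shape
        gr = g.reshape(n, o, h2 // 2, 2, w2 // 2, 2)
        return np.einsum("nchw,nohdwq->codq", x, gr, optimize=True)

    return vjp


defvjp(conv_transpose2x2, _ct_vjp_x, _ct_vjp_w, lambda ans, x, w, b: lambda g: g.sum((0, 2, 3)))


@primitive
def maxpool2x2(x):
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    r = x.reshape(n, c, h // 2, 2, w // 2, 2)
    return r.max(axis=(3, 5))


def _maxpool_vjp(ans, x):
    n, c, h, w = x.shape

    def vjp(g):
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(-1)  # first max wins on ties
        onehot = idx[..., None] == np.arange(4)
        gg = onehot * g[..., None]
        gg = gg.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gg.reshape(n, c, h, w)

    return vjp


defvjp(maxpool2x2, _maxpool_vjp)


@lru_cache(maxsize=256)
def _interp_matrix(src: int, dst: int) -> np.ndarray:
    """Row-interpolation matrix (dst, src), half-pixel-center convention."""
    m = np.zeros((dst, src))
    pos = (np.arange(dst) + 0.5) * src / dst - 0.5
    pos = np.clip(pos, 0.0, src - 1.0)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    frac = pos - lo
    m[np.arange(dst), lo] += 1.0 - frac
    m[np.arange(dst), hi] += frac
    return m


@primitive
def resize_bilinear(x, out_h, out_w):
    """Bilinear resampling of NCHW to (out_h, out_w)."""
    a = _interp_matrix(x.shape[2], out_h)
    b = _interp_matrix(x.shape[3], out_w)
    return np.einsum("ncij,pi,qj->ncpq", x, a, b, optimize=True)


def _resize_vjp(ans, x, out_h, out_w):
    a = _interp_matrix(x.shape[2], out_h)
    b = _interp_matrix(x.shape[3], out_w)

    def vjp(g):
        return np.einsum("ncpq,pi,qj->ncij", g, a, b, optimize=True)

    return vjp


defvjp(resize_bilinear, _resize_vjp)


def resize_nearest(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Nearest-neighbour resize of the trailing two axes (not differentiable;
    used for label maps, which are constants)."""
    h, w = x.shape[-2], x.shape[-1]
    ri = np.clip(np.floor((np.arange(out_h) + 0.5) * h / out_h), 0, h - 1).astype(int)
    ci = np.clip(np.floor((np.arange(out_w) + 0.5) * w / out_w), 0, w - 1).astype(int)
    return x[..., ri[:, None], ci[None, :]]


@primitive
def stop_gradient(x):
    return x


defvjp(stop_gradient, lambda ans, x: lambda g: np.zeros_like(x))


@primitive
def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


defvjp(sigmoid, lambda ans, x: lambda g: g * ans * (1.0 - ans))


def relu(x):
    return anp.maximum(x, 0.0)


def softmax(x, axis=-1):
    """Max-stabilized softmax along ``axis``."""
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


@primitive
def _bn_moments(x, gamma, beta, eps):
    m = x.mean(axis=(0, 2, 3), keepdims=True)
    v = ((x - m) ** 2).mean(axis=(0, 2, 3), keepdims=True)
    xn = (x - m) / np.sqrt(v + eps)
    return gamma[None, :, None, None] * xn + beta[None, :, None, None]


def _bn_vjp_x(ans, x, gamma, beta, eps):
    def vjp(g):
        m = x.mean(axis=(0, 2, 3), keepdims=True)
        v = ((x - m) ** 2).mean(axis=(0, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(v + eps)
        xn = (x - m) * inv
        gy = g * gamma[None, :, None, None]
        mg = gy.mean(axis=(0, 2, 3), keepdims=True)
        mgx = (gy * xn).mean(axis=(0, 2, 3), keepdims=True)
        return inv * (gy - mg - xn * mgx)

    return vjp


def _bn_vjp_gamma(ans, x, gamma, beta, eps):
    def vjp(g):
        m = x.mean(axis=(0, 2, 3), keepdims=True)
        v = ((x - m) ** 2).mean(axis=(0, 2, 3), keepdims=True)
        xn = (x - m) / np.sqrt(v + eps)
        return (g * xn).sum(axis=(0, 2, 3))

    return vjp


defvjp(
    _bn_moments,
    _bn_vjp_x,
    _bn_vjp_gamma,
    lambda ans, x, gamma, beta, eps: lambda g: g.sum(axis=(0, 2, 3)),
)


def batchnorm(x, gamma, beta, mode="batch", eps=1e-5):
    """Per-channel normalization of NCHW features.

    mode="batch": normalize by moments over (N, H, W) — the package's
    normalization at both train and test time (batch size is 1, so this is
    instance-style and deterministic).  mode="affine": scale-and-shift only,
    identity at initialization.
    """
    if mode == "affine":
        return gamma[None, :, None, None] * x + beta[None, :, None, None]
    return _bn_moments(x, gamma, beta, eps)
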