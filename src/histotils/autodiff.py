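"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the two-branch panoptic network needs:
3x3/1x1 convolution, ReLU, 2x2 max-pooling, nearest 2x upsampling, channel
concatenation, center cropping, (log-)softmax, elementwise arithmetic with
broadcasting, reductions, and a channel-mixing contraction for the
region-to-nucleus attention maps.  Gradients flow through a topologically
sorted tape.  All arrays are float64 NCHW.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._backward(t.grad)):
                if not parent.requires_grad or g is None:
                    continue
                g = _unbroadcast(g, parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # convenience operators
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __truediv__(self, other):
        return div(self, other)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# --- elementwise -------------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    return Tensor(a.data + b.data, parents=(a, b), backward=lambda g: (g, g))


def mul(a, b):
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        backward=lambda g: (g * b.data, g * a.data),
    )


def div(a, b):
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data / b.data,
        parents=(a, b),
        backward=lambda g: (g / b.data, -g * a.data / (b.data ** 2)),
    )


def log(a, eps=0.0):
    a = astensor(a)
    safe = a.data + eps
    return Tensor(np.log(safe), parents=(a,), backward=lambda g: (g / safe,))


def exp(a):
    a = astensor(a)
    out = np.exp(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * out,))


def relu(a):
    a = astensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, parents=(a,), backward=lambda g: (g * mask,))


# --- reductions --------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, a.data.shape).copy(),)

    return Tensor(out, parents=(a,), backward=back)


def tmean(a):
    a = astensor(a)
    n = a.data.size
    return Tensor(
        a.data.mean(),
        parents=(a,),
        backward=lambda g: (np.full(a.data.shape, g / n),),
    )


# --- softmax -----------------------------------------------------------------

def softmax(a, axis=1):
    a = astensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    return Tensor(y, parents=(a,), backward=back)


def log_softmax(a, axis=1):
    a = astensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    y = np.exp(out)

    def back(g):
        return (g - y * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, parents=(a,), backward=back)


# --- shape ops ---------------------------------------------------------------

def concat(tensors, axis=1):
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=back,
    )


def crop_center(a, out_h, out_w):
    """Center crop of the last two axes (NCHW)."""
    a = astensor(a)
    h, w = a.data.shape[-2:]
    y0, x0 = (h - out_h) // 2, (w - out_w) // 2

    def back(g):
        full = np.zeros(a.data.shape)
        full[..., y0 : y0 + out_h, x0 : x0 + out_w] = g
        return (full,)

    return Tensor(
        a.data[..., y0 : y0 + out_h, x0 : x0 + out_w].copy(),
        parents=(a,),
        backward=back,
    )


def upsample2(a):
    """Nearest-neighbor 2x upsampling of the last two axes."""
    a = astensor(a)
    out = a.data.repeat(2, axis=-2).repeat(2, axis=-1)

    def back(g):
        s = g.shape
        g4 = g.reshape(*s[:-2], s[-2] // 2, 2, s[-1] // 2, 2)
        return (g4.sum(axis=(-3, -1)),)

    return Tensor(out, parents=(a,), backward=back)


def maxpool2(a):
    """2x2 max pooling, stride 2 (ties resolve to the first maximum)."""
    a = astensor(a)
    n, c, h, w = a.data.shape
    win = a.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def back(g):
        gw = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gw.reshape(n, c, h, w),)

    return Tensor(out, parents=(a,), backward=back)


# --- convolution -------------------------------------------------------------

def conv2d(x, w, b, pad=None):
    """Same-size 2D convolution; ``w`` is (Cout, Cin, kh, kw)."""
    x, w, b = astensor(x), astensor(w), astensor(b)
    kh, kw = w.data.shape[2:]
    if pad is None:
        pad = kh // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, cin, hp, wp = xp.shape
    oh, ow = hp - kh + 1, wp - kw + 1
    out = np.zeros((n, w.data.shape[0], oh, ow))
    for i in range(kh):
        for j in range(kw):
            out += np.einsum(
                "nchw,oc->nohw",
                xp[:, :, i : i + oh, j : j + ow],
                w.data[:, :, i, j],
                optimize=True,
            )
    out += b.data[None, :, None, None]

    def back(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + oh, j : j + ow] += np.einsum(
                    "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                )
                gw[:, :, i, j] = np.einsum(
                    "nohw,nchw->oc",
                    g,
                    xp[:, :, i : i + oh, j : j + ow],
                    optimize=True,
                )
        gx = gxp[:, :, pad : pad + x.data.shape[2], pad : pad + x.data.shape[3]] if pad else gxp
        gb = g.sum(axis=(0, 2, 3))
        return gx, gw, gb

    return Tensor(out, parents=(x, w, b), backward=back)


def channel_mix(x, m):
    """Contract region channels against a (regions x classes) matrix.

    ``x`` is (N, R, H, W), ``m`` is (R, C); returns (N, C, H, W) with
    ``out[n,c] = sum_r x[n,r] * m[r,c]`` - the mixture underlying the
    class-specific attention maps.
    """
    x, m = astensor(x), astensor(m)
    out = np.einsum("nrhw,rc->nchw", x.data, m.data, optimize=True)

    def back(g):
        gx = np.einsum("nchw,rc->nrhw", g, m.data, optimize=True)
        gm = np.einsum("nrhw,nchw->rc", x.data, g, optimize=True)
        return gx, gm

    return Tensor(out, parents=(x, m), backward=back)


# --- optimizer ---------------------------------------------------------------

class Adam:
    """Adam with bias correction over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
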