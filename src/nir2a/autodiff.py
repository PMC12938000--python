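"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the tensor operations the enhancement network needs:
broadcasting arithmetic, matmul, strided convolution via im2col, batch/layer
normalization, softmax, nearest-neighbour upsampling, axis manipulation and
the two pixel losses.  Gradients are accumulated by walking the operation
graph in reverse topological order.  All floating point work is done in the
dtype of the inputs (float32 throughout the network; tests use float64 for
finite-difference checks).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor", "no_grad", "relu", "gelu", "sigmoid", "softmax", "matmul",
    "linear", "conv2d", "batchnorm2d", "layernorm", "upsample_nearest2",
    "concat", "reshape", "transpose", "roll", "l1_loss", "l2_loss",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager: ops performed inside build no graph (inference)."""

    def __enter__(self):
        self._prev_state = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev_state
        return False


def _as_float(data):
    a = np.asarray(data)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    return a


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape))
                 if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    """A numpy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev",
                 "name", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name=None):
        self.data = _as_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev) if _GRAD_ENABLED[0] else ()
        self.name = name
        self._grad_owned = False

    def _attach(self, bw):
        # inference mode: drop the closure so activations can be freed
        if _GRAD_ENABLED[0]:
            self._backward = bw

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.grad is not None})"

    def item(self):
        return float(self.data)

    # -- autograd ------------------------------------------------------
    def _accumulate(self, g):
        # first contribution is stored by reference (callers never mutate
        # their gradient argument); a second contribution copies on write
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self):
        # iterative postorder topological sort (no recursive closure: a
        # self-referential closure would keep the whole graph alive until
        # a cyclic-GC pass)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, expanded = stack.pop()
            if expanded:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        self._grad_owned = True
        # single-shot backward: each node's gradient and closure are freed
        # as soon as they have been consumed, so peak memory stays near the
        # forward-pass footprint
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            t._backward = None
            if t._prev:
                t.grad = None
                t._prev = ()

    def zero_grad(self):
        self.grad = None
        self._grad_owned = False

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))
        out._attach(_bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._attach(lambda g: self._accumulate(-g))
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __mul__(self, other):
        if np.isscalar(other):
            out = Tensor(self.data * other, self.requires_grad, (self,))
            out._attach(lambda g: self._accumulate(g * other))
            return out
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._attach(_bw)
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, other)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), x.requires_grad, (x,))
    out._attach(lambda g: x._accumulate(g * (x.data > 0)))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))
    out._attach(lambda g: x._accumulate(g * s * (1.0 - s)))
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    c = x.data / np.sqrt(2.0)
    cdf = 0.5 * (1.0 + erf(c))
    out = Tensor(x.data * cdf, x.requires_grad, (x,))
    pdf = np.exp(-0.5 * x.data * x.data) / np.sqrt(2.0 * np.pi)
    out._attach(lambda g: x._accumulate(g * (cdf + x.data * pdf)))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, x.requires_grad, (x,))

    def _bw(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        x._accumulate(p * (g - dot))
    out._attach(_bw)
    return out


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.matmul(a.data, b.data),
                 a.requires_grad or b.requires_grad, (a, b))

    def _bw(g):
        a._accumulate(_unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)),
                                   a.data.shape))
        b._accumulate(_unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g),
                                   b.data.shape))
    out._attach(_bw)
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ w + b with x (..., in), w (in, out), b (out,)."""
    out = matmul(x, w)
    if b is not None:
        out = out + b
    return out


# ---------------------------------------------------------------------------
# convolution (im2col)
# ---------------------------------------------------------------------------

def _gemm_acc(a: np.ndarray, b: np.ndarray, c: np.ndarray,
              beta: float = 1.0):
    """c := a @ b + beta * c in place (C-contiguous float32 fast path)."""
    if (a.dtype == b.dtype == c.dtype == np.float32
            and a.flags.c_contiguous and b.flags.c_contiguous
            and c.flags.c_contiguous):
        from scipy.linalg import blas as sblas
        # row-major X is column-major X^T: compute c^T = b^T a^T + beta c^T
        sblas.sgemm(1.0, b.T, a.T, beta=beta, c=c.T, overwrite_c=True)
    else:
        if beta == 0.0:
            c[:] = a @ b
        else:
            c *= beta
            c += a @ b


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           padding: int = 1) -> Tensor:
    """2-D convolution, channels-last: x (N,H,W,C), w (F,C,k,k), b (F,).

    Computed as k*k shifted matmuls rather than via an explicit im2col
    patch matrix.  For stride 1 each kernel offset is a single contiguous
    GEMM over the flattened padded plane: offset reads are a shifted flat
    slice, and reads that cross an image-block boundary only ever touch
    rows whose output is discarded or whose gradient is zero, so the
    result is exact.
    """
    if stride == 1:
        return _conv2d_s1(x, w, b, padding)
    return _conv2d_strided(x, w, b, stride, padding)


def _conv2d_s1(x: Tensor, w: Tensor, b: Tensor, p: int) -> Tensor:
    n, h, wd, c = x.data.shape
    f, _, k, _ = w.data.shape
    hp, wp = h + 2 * p, wd + 2 * p
    oh = hp - k + 1
    ow = wp - k + 1
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    flat = xp.reshape(n * hp * wp, c)
    total = n * hp * wp
    y = np.empty((total, f), dtype=x.data.dtype)
    wk = [[np.ascontiguousarray(w.data[:, :, i, j].T) for j in range(k)]
          for i in range(k)]
    for i in range(k):
        for j in range(k):
            sh = i * wp + j
            _gemm_acc(flat[sh:] if sh else flat, wk[i][j],
                      y[:total - sh] if sh else y,
                      beta=0.0 if (i == 0 and j == 0) else 1.0)
    out_hw = y.reshape(n, hp, wp, f)[:, :oh, :ow] + b.data
    out = Tensor(out_hw, x.requires_grad or w.requires_grad or
                 b.requires_grad, (x, w, b))

    def _bw(g):
        b._accumulate(g.sum(axis=(0, 1, 2)))
        gfull = np.zeros((n, hp, wp, f), dtype=g.dtype)
        gfull[:, :oh, :ow] = g
        gflat = gfull.reshape(total, f)
        need_dx = x.requires_grad or x._prev
        dflat = np.empty_like(flat) if need_dx else None
        dw = np.empty_like(w.data)
        for i in range(k):
            for j in range(k):
                sh = i * wp + j
                gs = gflat[:total - sh] if sh else gflat
                dw[:, :, i, j] = gs.T @ (flat[sh:] if sh else flat)
                if need_dx:
                    _gemm_acc(gs, np.ascontiguousarray(w.data[:, :, i, j]),
                              dflat[sh:] if sh else dflat,
                              beta=0.0 if (i == 0 and j == 0) else 1.0)
        w._accumulate(dw)
        if need_dx:
            x._accumulate(dflat.reshape(n, hp, wp, c)[:, p:p + h, p:p + wd])
    out._attach(_bw)
    return out


def _conv2d_strided(x: Tensor, w: Tensor, b: Tensor, s: int,
                    p: int) -> Tensor:
    n, h, wd, c = x.data.shape
    f, _, k, _ = w.data.shape
    oh = (h + 2 * p - k) // s + 1
    ow = (wd + 2 * p - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    y = np.empty((n, oh, ow, f), dtype=x.data.dtype)
    y[:] = b.data
    for i in range(k):
        for j in range(k):
            v = xp[:, i:i + s * oh:s, j:j + s * ow:s, :]
            y += v @ w.data[:, :, i, j].T
    out = Tensor(y, x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def _bw(g):
        b._accumulate(g.sum(axis=(0, 1, 2)))
        gm = np.ascontiguousarray(g).reshape(-1, f)
        dw = np.empty_like(w.data)
        need_dx = x.requires_grad or x._prev
        dxp = np.zeros_like(xp) if need_dx else None
        for i in range(k):
            for j in range(k):
                v = xp[:, i:i + s * oh:s, j:j + s * ow:s, :]
                vc = np.ascontiguousarray(v).reshape(-1, c)
                dw[:, :, i, j] = gm.T @ vc
                if need_dx:
                    dxp[:, i:i + s * oh:s, j:j + s * ow:s, :] += \
                        g @ w.data[:, :, i, j]
        w._accumulate(dw)
        if need_dx:
            x._accumulate(dxp[:, p:p + h, p:p + wd, :])
    out._attach(_bw)
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Channel batch-norm on (N,H,W,C); running stats updated in place."""
    axes = (0, 1, 2)
    gshape = (-1,)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(gshape)) * inv.reshape(gshape)
    y = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
    out = Tensor(y, x.requires_grad or gamma.requires_grad or
                 beta.requires_grad, (x, gamma, beta))

    def _bw(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gi = gamma.data.reshape(gshape) * inv.reshape(gshape)
        if training:
            gmean = g.mean(axis=axes, keepdims=True)
            gxhat = (g * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(gi * (g - gmean - xhat * gxhat))
        else:
            x._accumulate(gi * g)
    out._attach(_bw)
    return out


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor,
              eps: float = 1e-5) -> Tensor:
    """Layer norm over the last axis of x (..., D)."""
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    y = gamma.data * xhat + beta.data
    out = Tensor(y, x.requires_grad or gamma.requires_grad or
                 beta.requires_grad, (x, gamma, beta))

    def _bw(g):
        red = tuple(range(g.ndim - 1))
        gamma._accumulate((g * xhat).sum(axis=red))
        beta._accumulate(g.sum(axis=red))
        gx = g * gamma.data
        gmean = gx.mean(axis=-1, keepdims=True)
        gdot = (gx * xhat).mean(axis=-1, keepdims=True)
        x._accumulate(inv * (gx - gmean - xhat * gdot))
    out._attach(_bw)
    return out


# ---------------------------------------------------------------------------
# shape / layout ops
# ---------------------------------------------------------------------------

def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of (N,H,W,C)."""
    n, h, w, c = x.data.shape
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    out = Tensor(y, x.requires_grad, (x,))

    def _bw(g):
        x._accumulate(g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))
    out._attach(_bw)
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        start = 0
        for t, sz in zip(tensors, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, start + sz)
            t._accumulate(g[tuple(idx)])
            start += sz
    out._attach(_bw)
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), x.requires_grad, (x,))
    out._attach(lambda g: x._accumulate(g.reshape(x.data.shape)))
    return out


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    out = Tensor(np.ascontiguousarray(x.data.transpose(axes)),
                 x.requires_grad, (x,))
    out._attach(lambda g: x._accumulate(g.transpose(inv)))
    return out


def roll(x: Tensor, shift, axes) -> Tensor:
    out = Tensor(np.roll(x.data, shift, axis=axes), x.requires_grad, (x,))
    neg = tuple(-s for s in shift) if np.iterable(shift) else -shift
    out._attach(lambda g: x._accumulate(np.roll(g, neg, axis=axes)))
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, dtype=pred.dtype)
    out = Tensor(np.abs(diff).mean(), pred.requires_grad, (pred,))
    out._attach(lambda g: pred._accumulate(g * np.sign(diff) / diff.size))
    return out


def l2_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, dtype=pred.dtype)
    out = Tensor((diff * diff).mean(), pred.requires_grad, (pred,))
    out._attach(lambda g: pred._accumulate(g * 2.0 * diff / diff.size))
    return out
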