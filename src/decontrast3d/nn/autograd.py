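"""Tape-based reverse-mode autodiff over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operation that
produced it; ``backward()`` walks the tape in reverse topological order.
Tensors are float64 by default (tight gradient checks); the
:func:`default_dtype` context switches new tensors to float32 where speed
matters (the training loop).
"""

from __future__ import annotations

import contextlib
from itertools import product

import numpy as np

_GRAD_ENABLED = True
_DEFAULT_DTYPE = np.float64


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def default_dtype(dtype):
    """Set the dtype new tensors are cast to (float64 default).

    float32 roughly halves training time and memory; float64 is kept as
    the default so finite-difference gradient checks stay tight.
    """
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction of derived tensors -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p):
        p = float(p)
        out_data = self.data**p

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    # -- reductions and reshaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(src_shape))

        return Tensor._make(out_data, (self,), bw)

    def flatten(self):
        return self.reshape(-1)

    # -- nonlinearities --------------------------------------------------------
    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            if self.requires_grad:
                self._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi] (hard clip)."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis (channel axis 0 in this package)."""
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, bw)


# -- spatial ops ---------------------------------------------------------------


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding=None) -> Tensor:
    """3D cross-correlation, layout (C, X, Y, Z) / weights (Cout, Cin, kx, ky, kz).

    im2col formulation: kernel-offset slices are gathered into one matrix so
    the whole convolution (and both gradient contractions) is a single GEMM.
    """
    kx, ky, kz = w.shape[2:]
    if padding is None:
        padding = (kx // 2, ky // 2, kz // 2)
    px, py, pz = padding
    s = int(stride)
    cin, X, Y, Z = x.shape
    cout = w.shape[0]
    if w.shape[1] != cin:
        raise ValueError(f"weight expects {w.shape[1]} input channels, got {cin}")
    Xo = (X + 2 * px - kx) // s + 1
    Yo = (Y + 2 * py - ky) // s + 1
    Zo = (Z + 2 * pz - kz) // s + 1
    if min(Xo, Yo, Zo) < 1:
        raise ValueError(
            f"input {x.shape[1:]} too small for kernel {(kx, ky, kz)} "
            f"stride {s} padding {padding}"
        )
    xp = np.pad(x.data, ((0, 0), (px, px), (py, py), (pz, pz)))
    offsets = list(product(range(kx), range(ky), range(kz)))
    n_out = Xo * Yo * Zo
    cols = np.empty((len(offsets), cin, n_out), dtype=xp.dtype)
    for oi, (dx, dy, dz) in enumerate(offsets):
        cols[oi] = xp[
            :, dx : dx + s * Xo : s, dy : dy + s * Yo : s, dz : dz + s * Zo : s
        ].reshape(cin, n_out)
    cols = cols.reshape(len(offsets) * cin, n_out)
    # weight plane layout matches cols: offsets major, channels minor
    w2d = np.ascontiguousarray(
        w.data.transpose(2, 3, 4, 1, 0).reshape(len(offsets) * cin, cout)
    )
    out = (w2d.T @ cols).reshape(cout, Xo, Yo, Zo) + b.data.reshape(-1, 1, 1, 1)

    def bw(g):
        g2d = g.reshape(cout, n_out)
        if w.requires_grad:
            gw = (cols @ g2d.T).reshape(kx, ky, kz, cin, cout)
            w._accum(np.ascontiguousarray(gw.transpose(4, 3, 0, 1, 2)))
        if b.requires_grad:
            b._accum(g2d.sum(axis=1))
        if x.requires_grad:
            gcols = (w2d @ g2d).reshape(len(offsets), cin, Xo, Yo, Zo)
            gxp = np.zeros_like(xp)
            for oi, (dx, dy, dz) in enumerate(offsets):
                gxp[
                    :, dx : dx + s * Xo : s, dy : dy + s * Yo : s, dz : dz + s * Zo : s
                ] += gcols[oi]
            x._accum(gxp[:, px : px + X, py : py + Y, pz : pz + Z])

    return Tensor._make(out, (x, w, b), bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with affine parameters.

    The natural choice at mini-batch size 1, where batch statistics collapse.
    """
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gs = gamma.data.reshape(-1, 1, 1, 1)
    out = gs * xhat + beta.data.reshape(-1, 1, 1, 1)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gh = g * gs
            m1 = gh.mean(axis=axes, keepdims=True)
            m2 = (gh * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv_std * (gh - m1 - xhat * m2))

    return Tensor._make(out, (x, gamma, beta), bw)


def _linear_up_indices(n: int):
    """Index/weight tables for 2x linear upsampling of a length-n axis.

    Output sample i sits at source coordinate (i + 0.5)/2 - 0.5 (edge-aligned
    half-voxel convention); edges clamp.
    """
    i = np.arange(2 * n)
    src = (i + 0.5) / 2.0 - 0.5
    i0 = np.floor(src).astype(int)
    w1 = src - i0
    lo = np.clip(i0, 0, n - 1)
    hi = np.clip(i0 + 1, 0, n - 1)
    return lo, hi, w1


def upsample2x_linear(x: Tensor) -> Tensor:
    """Trilinear 2x upsampling of the three spatial axes of (C, X, Y, Z)."""
    tables = []
    data = x.data
    for axis in (1, 2, 3):
        n = data.shape[axis]
        lo, hi, w1 = _linear_up_indices(n)
        tables.append((axis, lo, hi, w1))
        shape = [1] * data.ndim
        shape[axis] = 2 * n
        w1b = w1.reshape(shape)
        data = (1.0 - w1b) * np.take(data, lo, axis=axis) + w1b * np.take(
            data, hi, axis=axis
        )

    def bw(g):
        if not x.requires_grad:
            return
        for axis, lo, hi, w1 in reversed(tables):
            n = len(lo) // 2
            gm = np.moveaxis(g, axis, 0)
            acc = np.zeros((n,) + gm.shape[1:])
            wshape = (len(w1),) + (1,) * (gm.ndim - 1)
            w1b = w1.reshape(wshape)
            np.add.at(acc, lo, gm * (1.0 - w1b))
            np.add.at(acc, hi, gm * w1b)
            g = np.moveaxis(acc, 0, axis)
        x._accum(g)

    return Tensor._make(data, (x,), bw)
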