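"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the models in this package.  Every
primitive registers, per input, a vector-Jacobian-product (VJP) callable that
is itself *built out of primitives*, so gradients can be differentiated again
("double backward").  That property is what makes the exact second-order
outer gradient of the bi-level meta objective computable: the inner-loop
adapted parameters are graph nodes, and differentiating the primary loss
through them requires back-propagating through a backward pass.

Only what the package needs is implemented: elementwise arithmetic,
matmul with broadcasting, reshapes/transposes/concatenation/slicing,
reductions, a handful of nonlinearities, and the im2col/col2im pair that
expresses convolution as matrix multiplication.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor", "astensor", "parameter", "no_grad", "grad",
    "exp", "log", "sigmoid", "softplus", "erf", "relu", "gelu",
    "matmul", "transpose", "reshape", "concat", "tsum", "tmean", "tmax_const",
    "stop_gradient", "softmax", "log_softmax", "pad2d", "im2col", "col2im",
]

_GRAD_ENABLED = True
_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Working precision for constants and parameters.

    float64 (the default) is required by the finite-difference oracles;
    float32 roughly halves training time on the desk-scale profiles.
    """
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def working_dtype(dtype):
    """Temporarily switch the default dtype."""
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (constants come out)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the tape entry that produced it."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjps=(),
                 name: str | None = None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._vjps = tuple(vjps)
        self.name = name

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def copy(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=self.requires_grad,
                      name=self.name)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}, name={self.name})"

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(astensor(other)))

    def __rsub__(self, other):
        return add(astensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, astensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, astensor(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def astensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=_DEFAULT_DTYPE))


def parameter(data, name: str | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=_DEFAULT_DTYPE), requires_grad=True,
                  name=name)


def _make(data, parents, vjps, name=None) -> Tensor:
    """Create an op output; record the tape entry only when tracing is on."""
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, vjps=vjps, name=name)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce a cotangent back to the shape of an input
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# elementwise primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _make(a.data + b.data, (a, b),
                 (lambda g: _unbroadcast(g, a.shape),
                  lambda g: _unbroadcast(g, b.shape)))


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, (a,), (lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _make(a.data * b.data, (a, b),
                 (lambda g: _unbroadcast(mul(g, b), a.shape),
                  lambda g: _unbroadcast(mul(g, a), b.shape)))


def power(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return _make(a.data ** p, (a,),
                 (lambda g: mul(g, mul(astensor(p), power(a, p - 1.0))),))


def exp(a: Tensor) -> Tensor:
    return _make(np.exp(a.data), (a,), (lambda g: mul(g, exp(a)),))


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), (lambda g: mul(g, power(a, -1.0)),))


def sigmoid(a: Tensor) -> Tensor:
    return _make(_sp.expit(a.data), (a,),
                 (lambda g: mul(g, mul(sigmoid(a), sigmoid(neg(a)))),))


def softplus(a: Tensor) -> Tensor:
    """log(1 + e^a), computed stably."""
    return _make(np.logaddexp(0.0, a.data), (a,),
                 (lambda g: mul(g, sigmoid(a)),))


def erf(a: Tensor) -> Tensor:
    c = 2.0 / np.sqrt(np.pi)
    return _make(_sp.erf(a.data), (a,),
                 (lambda g: mul(g, mul(astensor(c), exp(neg(mul(a, a))))),))


def relu(a: Tensor) -> Tensor:
    mask = (a.data > 0).astype(a.data.dtype)
    return _make(a.data * mask, (a,), (lambda g: mul(g, astensor(mask)),))


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    half = astensor(0.5)
    return mul(mul(half, a), add(astensor(1.0), erf(mul(a, astensor(1.0 / np.sqrt(2.0))))))


def stop_gradient(a: Tensor) -> Tensor:
    return Tensor(a.data)


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    old = a.shape
    return _make(a.data.reshape(shape), (a,), (lambda g: reshape(g, old),))


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (a,), (lambda g: transpose(g, inv),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return getitem(g, tuple(sl))
        return vjp

    return _make(data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def getitem(a: Tensor, idx) -> Tensor:
    shape = a.shape
    return _make(a.data[idx], (a,), (lambda g: scatter(g, idx, shape),))


def scatter(g: Tensor, idx, shape) -> Tensor:
    """Adjoint of basic indexing: place ``g`` into zeros of ``shape``."""
    out = np.zeros(shape, dtype=g.data.dtype)
    np.add.at(out, idx, g.data)
    return _make(out, (g,), (lambda h: getitem(h, idx),))


def pad2d(a: Tensor, pad: int) -> Tensor:
    """Zero-pad the trailing two axes of a (..., H, W) tensor."""
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    sl = (Ellipsis, slice(pad, a.shape[-2] + pad), slice(pad, a.shape[-1] + pad))
    return _make(np.pad(a.data, width), (a,), (lambda g: getitem(g, sl),))


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)
    shape = a.shape

    def vjp(g):
        if axis is None:
            return mul(reshape(g, (1,) * len(shape)), astensor(np.ones(shape, dtype=a.dtype)))
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % len(shape) for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(shape))
            g = reshape(g, kshape)
        return mul(g, astensor(np.ones(shape, dtype=a.dtype)))

    return _make(data, (a,), (vjp,))


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        denom = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        denom = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), astensor(1.0 / denom))


def tmax_const(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    """Maximum of ``a`` as a constant (no gradient); for softmax shifts."""
    return Tensor(a.data.max(axis=axis, keepdims=keepdims))


# ---------------------------------------------------------------------------
# matmul
# ---------------------------------------------------------------------------

def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(t, axes)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    data = np.matmul(a.data, b.data)

    def vjp_a(g):
        ga = matmul(g, _swap_last(b))
        return _unbroadcast(ga, a.shape) if ga.shape != a.shape else ga

    def vjp_b(g):
        gb = matmul(_swap_last(a), g)
        return _unbroadcast(gb, b.shape) if gb.shape != b.shape else gb

    return _make(data, (a, b), (vjp_a, vjp_b))


# ---------------------------------------------------------------------------
# softmax family (composed; stable via constant shift)
# ---------------------------------------------------------------------------

def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = add(a, neg(tmax_const(a, axis=axis, keepdims=True)))
    e = exp(z)
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = add(a, neg(tmax_const(a, axis=axis, keepdims=True)))
    return add(z, neg(log(tsum(exp(z), axis=axis, keepdims=True))))


# ---------------------------------------------------------------------------
# im2col / col2im — convolution as matmul; the two are mutual adjoints
# ---------------------------------------------------------------------------

def _im2col_data(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    B, C, H, W = x.shape
    oh = (H - kh) // sh + 1
    ow = (W - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    win = np.lib.stride_tricks.as_strided(
        x, (B, C, oh, ow, kh, kw), (s0, s1, s2 * sh, s3 * sw, s2, s3))
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh * ow, C * kh * kw).copy()


def _col2im_data(cols: np.ndarray, xshape, kh, kw, sh, sw) -> np.ndarray:
    B, C, H, W = xshape
    oh = (H - kh) // sh + 1
    ow = (W - kw) // sw + 1
    out = np.zeros(xshape, dtype=cols.dtype)
    c6 = cols.reshape(B, oh, ow, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += c6[:, :, :, :, i, j]
    return out


def im2col(x: Tensor, kh: int, kw: int, sh: int = 1, sw: int = 1) -> Tensor:
    shape = x.shape
    return _make(_im2col_data(x.data, kh, kw, sh, sw), (x,),
                 (lambda g: col2im(g, shape, kh, kw, sh, sw),))


def col2im(cols: Tensor, xshape, kh: int, kw: int, sh: int = 1, sw: int = 1) -> Tensor:
    return _make(_col2im_data(cols.data, xshape, kh, kw, sh, sw), (cols,),
                 (lambda g: im2col(g, kh, kw, sh, sw),))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _topo(output: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, wrt: Sequence[Tensor], create_graph: bool = False,
         seed: Tensor | None = None) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``wrt`` tensors.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes, so they can be differentiated again (needed for second-order
    meta-gradients).  Inputs that the output does not depend on get zero
    gradients of the appropriate shape.
    """
    if not output.requires_grad:
        return [Tensor(np.zeros(w.shape, dtype=w.dtype)) for w in wrt]
    if seed is None:
        seed = Tensor(np.ones(output.shape, dtype=output.data.dtype))
    cot: dict[int, Tensor] = {id(output): seed}
    order = _topo(output)
    wrt_ids = {id(w) for w in wrt}

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(order):
            g = cot.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                contrib = vjp(g)
                prev = cot.get(id(parent))
                cot[id(parent)] = contrib if prev is None else add(prev, contrib)
            # keep cotangents of requested nodes even if popped above
            if id(node) in wrt_ids:
                cot[id(node)] = g

    out = []
    for w in wrt:
        g = cot.get(id(w))
        if g is None:
            g = Tensor(np.zeros(w.shape, dtype=w.dtype))
        out.append(g)
    return out
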