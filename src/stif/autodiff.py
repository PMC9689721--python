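"""Minimal reverse-mode automatic differentiation over numpy arrays.

The forecasting model is small enough (tens of parameter matrices, batch
sizes in the tens) that a vectorized numpy tape is both fast and exactly
reproducible.  Every function in this module accepts either a :class:`Tensor`
(recorded on the tape) or a plain ``numpy.ndarray``/scalar (evaluated
eagerly), so model code written once serves both training and inference.

Gradient correctness is pinned down by finite-difference tests; see
``tests/test_autodiff.py``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "value_of",
    "exp",
    "elu",
    "minimum_const",
    "where_const",
    "tsum",
    "tmax_detached",
    "reshape",
    "swapaxes",
    "softmax",
    "layer_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape wrapping a float64 ndarray."""

    # make numpy defer binary ops to our reflected operators
    __array_ufunc__ = None
    __slots__ = ("value", "grad", "_backward", "_parents")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape})"

    # ---- autograd ------------------------------------------------------
    def backward(self):
        """Accumulate gradients of self (must be scalar) into the tape."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- operators -----------------------------------------------------
    def __add__(self, other):
        return _add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return _mul_const(self, -1.0)

    def __sub__(self, other):
        return _add(self, _negate(other))

    def __rsub__(self, other):
        return _add(_negate(self), other)

    def __mul__(self, other):
        return _mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return _mul(self, _pow_const(other, -1.0))
        return _mul_const(self, 1.0 / np.asarray(other, dtype=np.float64))

    def __rtruediv__(self, other):
        return _mul(_pow_const(self, -1.0), other)

    def __pow__(self, p):
        return _pow_const(self, float(p))

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)


def value_of(x):
    """Plain ndarray view of a Tensor or array-like."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _is_node(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def _acc(t: Tensor, g: np.ndarray) -> None:
    """Lazily accumulate a gradient contribution into a tensor."""
    t.grad = g if t.grad is None else t.grad + g


# ---- primitive ops ------------------------------------------------------

def _negate(x):
    if isinstance(x, Tensor):
        return _mul_const(x, -1.0)
    return -np.asarray(x, dtype=np.float64)


def _add(a, b):
    if not _is_node(a, b):
        return np.asarray(a, dtype=np.float64) + np.asarray(b, dtype=np.float64)
    av, bv = value_of(a), value_of(b)
    out_val = av + bv
    parents = tuple(x for x in (a, b) if isinstance(x, Tensor))

    def backward(g):
        if isinstance(a, Tensor):
            _acc(a, _unbroadcast(g, av.shape))
        if isinstance(b, Tensor):
            _acc(b, _unbroadcast(g, bv.shape))

    return Tensor(out_val, parents, backward)


def _mul(a, b):
    if not _is_node(a, b):
        return np.asarray(a, dtype=np.float64) * np.asarray(b, dtype=np.float64)
    av, bv = value_of(a), value_of(b)
    out_val = av * bv
    parents = tuple(x for x in (a, b) if isinstance(x, Tensor))

    def backward(g):
        if isinstance(a, Tensor):
            _acc(a, _unbroadcast(g * bv, av.shape))
        if isinstance(b, Tensor):
            _acc(b, _unbroadcast(g * av, bv.shape))

    return Tensor(out_val, parents, backward)


def _mul_const(a: Tensor, c):
    out_val = a.value * c

    def backward(g):
        _acc(a, _unbroadcast(g * c, a.value.shape))

    return Tensor(out_val, (a,), backward)


def _pow_const(a, p: float):
    if not isinstance(a, Tensor):
        return np.asarray(a, dtype=np.float64) ** p
    out_val = a.value ** p

    def backward(g):
        _acc(a, _unbroadcast(g * p * a.value ** (p - 1.0), a.value.shape))

    return Tensor(out_val, (a,), backward)


def matmul(a, b):
    if not _is_node(a, b):
        return np.asarray(a, dtype=np.float64) @ np.asarray(b, dtype=np.float64)
    # promote 1-D operands to 2-D so only the (...,n,m) @ (...,m,p) case
    # needs a gradient rule; squeeze the result back afterwards
    a_vec = value_of(a).ndim == 1
    b_vec = value_of(b).ndim == 1
    if a_vec:
        a = reshape(a, (1, -1)) if isinstance(a, Tensor) else np.asarray(a, dtype=np.float64)[None, :]
    if b_vec:
        b = reshape(b, (-1, 1)) if isinstance(b, Tensor) else np.asarray(b, dtype=np.float64)[:, None]
    out = _matmul2(a, b)
    if a_vec and b_vec:
        return reshape(out, ())
    if a_vec:
        shp = value_of(out).shape
        return reshape(out, shp[:-2] + (shp[-1],))
    if b_vec:
        shp = value_of(out).shape
        return reshape(out, shp[:-1])
    return out


def _matmul2(a, b):
    av, bv = value_of(a), value_of(b)
    out_val = av @ bv
    parents = tuple(x for x in (a, b) if isinstance(x, Tensor))

    def backward(g):
        if isinstance(a, Tensor):
            _acc(a, _unbroadcast(g @ np.swapaxes(bv, -1, -2), av.shape))
        if isinstance(b, Tensor):
            _acc(b, _unbroadcast(np.swapaxes(av, -1, -2) @ g, bv.shape))

    return Tensor(out_val, parents, backward)


def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(np.asarray(x, dtype=np.float64))
    out_val = np.exp(x.value)

    def backward(g):
        _acc(x, g * out_val)

    return Tensor(out_val, (x,), backward)


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x>0, alpha*(e^x - 1) otherwise."""
    if not isinstance(x, Tensor):
        v = np.asarray(x, dtype=np.float64)
        return np.where(v > 0, v, alpha * np.expm1(v))
    v = x.value
    out_val = np.where(v > 0, v, alpha * np.expm1(v))

    def backward(g):
        _acc(x, g * np.where(v > 0, 1.0, alpha * np.exp(v)))

    return Tensor(out_val, (x,), backward)


def minimum_const(x, cap: float):
    """Elementwise min(x, cap); gradient is blocked where the cap binds."""
    if not isinstance(x, Tensor):
        return np.minimum(np.asarray(x, dtype=np.float64), cap)
    out_val = np.minimum(x.value, cap)

    def backward(g):
        _acc(x, g * (x.value <= cap))

    return Tensor(out_val, (x,), backward)


def where_const(cond: np.ndarray, x, fill: float):
    """x where cond is truthy, the constant `fill` elsewhere."""
    cond = np.asarray(cond, dtype=bool)
    if not isinstance(x, Tensor):
        return np.where(cond, np.asarray(x, dtype=np.float64), fill)
    out_val = np.where(cond, x.value, fill)

    def backward(g):
        _acc(x, _unbroadcast(g * cond, x.value.shape))

    return Tensor(out_val, (x,), backward)


def tsum(x, axis=None, keepdims: bool = False):
    if not isinstance(x, Tensor):
        return np.sum(np.asarray(x, dtype=np.float64), axis=axis, keepdims=keepdims)
    out_val = np.sum(x.value, axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is None:
            _acc(x, np.broadcast_to(g, x.value.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _acc(x, np.broadcast_to(g, x.value.shape))

    return Tensor(out_val, (x,), backward)


def tmax_detached(x, axis, keepdims: bool = True):
    """max over axis treated as a constant (the softmax stability shift)."""
    return np.max(value_of(x), axis=axis, keepdims=keepdims)


def reshape(x, shape):
    if not isinstance(x, Tensor):
        return np.reshape(np.asarray(x, dtype=np.float64), shape)
    old = x.value.shape
    out_val = x.value.reshape(shape)

    def backward(g):
        _acc(x, g.reshape(old))

    return Tensor(out_val, (x,), backward)


def swapaxes(x, a1: int, a2: int):
    if not isinstance(x, Tensor):
        return np.swapaxes(np.asarray(x, dtype=np.float64), a1, a2)
    out_val = np.swapaxes(x.value, a1, a2)

    def backward(g):
        _acc(x, np.swapaxes(g, a1, a2))

    return Tensor(out_val, (x,), backward)


def softmax(x, axis: int = -1):
    """Numerically stable row softmax (the classical attention normalizer)."""
    shifted = x - tmax_detached(x, axis=axis, keepdims=True)
    e = exp(shifted)
    return e / tsum(e, axis=axis, keepdims=True)


def layer_norm(x, axis: int, scale, shift, eps: float = 1e-5):
    """Normalize x to zero mean / unit variance over `axis`, then affine map.

    Uses the population (1/n) variance, matching the standard layer-norm
    convention; eps guards the degenerate constant-input case.
    """
    n = value_of(x).shape[axis]
    mu = tsum(x, axis=axis, keepdims=True) / n
    xc = x - mu
    var = tsum(xc * xc, axis=axis, keepdims=True) / n
    inv = (var + eps) ** -0.5
    return xc * inv * scale + shift
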