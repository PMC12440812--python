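"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine providing exactly the primitives the
potential-energy models in this package need: elementwise arithmetic with
broadcasting, `erf`, stable softplus/log-sum-exp, matrix products, gather /
scatter-add (segment sums over graph edges), concatenation, and a linear
``solve`` whose adjoint is again a ``solve`` (implicit differentiation).

Every vector-Jacobian product is itself built from these primitives, so
``grad(..., create_graph=True)`` yields differentiable gradients and
second-order quantities (gradients of force-matching losses) come out of the
same machinery.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf as _np_erf
from scipy.special import expit as _expit

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "grad",
    "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "sqrt", "sin", "cos", "tanh", "erf",
    "sigmoid", "softplus", "logaddexp", "silu",
    "matmul", "linear", "transpose", "reshape", "tsum",
    "gather", "scatter_add", "concatenate", "where_const",
    "solve", "broadcast_to",
]


class Tensor:
    """A node in the computation graph wrapping a float ndarray."""

    __slots__ = ("data", "parents", "vjps", "requires_grad")

    def __init__(self, data, parents=(), vjps=(), requires_grad=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjps = vjps
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        self.requires_grad = requires_grad

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return gather(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    @property
    def T(self):
        return transpose(self)


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum a gradient back down to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    # remove leading broadcast axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


def broadcast_to(a, shape) -> Tensor:
    a = _t(a)
    out = np.broadcast_to(a.data, shape)
    return Tensor(out, (a,), (lambda g, sh=a.shape: _unbroadcast(g, sh),))


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return Tensor(
        a.data + b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(g, b.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return Tensor(
        a.data - b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape),
         lambda g: _unbroadcast(neg(g), b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return Tensor(
        a.data * b.data,
        (a, b),
        (lambda g: _unbroadcast(mul(g, b), a.shape),
         lambda g: _unbroadcast(mul(g, a), b.shape)),
    )


def div(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return Tensor(
        a.data / b.data,
        (a, b),
        (lambda g: _unbroadcast(div(g, b), a.shape),
         lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)),
    )


def neg(a) -> Tensor:
    a = _t(a)
    return Tensor(-a.data, (a,), (lambda g: neg(g),))


def power(a, p: float) -> Tensor:
    a = _t(a)
    p = float(p)
    return Tensor(a.data ** p, (a,),
                  (lambda g: mul(g, mul(p, power(a, p - 1.0))),))


# ---------------------------------------------------------------------------
# elementwise transcendentals
# ---------------------------------------------------------------------------

def exp(a) -> Tensor:
    a = _t(a)
    return Tensor(np.exp(a.data), (a,), (lambda g: mul(g, exp(a)),))


def log(a) -> Tensor:
    a = _t(a)
    return Tensor(np.log(a.data), (a,), (lambda g: div(g, a),))


def sqrt(a) -> Tensor:
    a = _t(a)
    return Tensor(np.sqrt(a.data), (a,),
                  (lambda g: div(g, mul(2.0, sqrt(a))),))


def sin(a) -> Tensor:
    a = _t(a)
    return Tensor(np.sin(a.data), (a,), (lambda g: mul(g, cos(a)),))


def cos(a) -> Tensor:
    a = _t(a)
    return Tensor(np.cos(a.data), (a,), (lambda g: neg(mul(g, sin(a))),))


def tanh(a) -> Tensor:
    a = _t(a)
    return Tensor(np.tanh(a.data), (a,),
                  (lambda g: mul(g, sub(1.0, mul(tanh(a), tanh(a)))),))


_TWO_OVER_SQRT_PI = 2.0 / math.sqrt(math.pi)


def erf(a) -> Tensor:
    a = _t(a)
    return Tensor(_np_erf(a.data), (a,),
                  (lambda g: mul(g, mul(_TWO_OVER_SQRT_PI,
                                        exp(neg(mul(a, a))))),))


def sigmoid(a) -> Tensor:
    a = _t(a)

    def vjp(g):
        s = sigmoid(a)
        return mul(g, mul(s, sub(1.0, s)))

    return Tensor(_expit(a.data), (a,), (vjp,))


def softplus(a) -> Tensor:
    """log(1 + e^x), overflow-safe; d/dx = sigmoid(x)."""
    a = _t(a)
    return Tensor(np.logaddexp(0.0, a.data), (a,),
                  (lambda g: mul(g, sigmoid(a)),))


def logaddexp(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    return Tensor(
        np.logaddexp(a.data, b.data),
        (a, b),
        (lambda g: _unbroadcast(mul(g, sigmoid(sub(a, b))), a.shape),
         lambda g: _unbroadcast(mul(g, sigmoid(sub(b, a))), b.shape)),
    )


def _silu_d2(a) -> Tensor:
    """Second derivative of silu: s(1-s)(2 + x(1-2s)); slow-path vjp."""
    a = _t(a)
    s = _expit(a.data)
    val = s * (1 - s) * (2.0 + a.data * (1.0 - 2.0 * s))

    def vjp(g):
        # third derivative f''' = s'[3(1-2s) + x((1-2s)^2 - 2s')],
        # assembled from sigmoid primitives (rarely hit)
        sg = sigmoid(a)
        sp = mul(sg, sub(1.0, sg))                 # s'
        one_m2 = sub(1.0, mul(2.0, sg))            # 1 - 2s
        inner = add(mul(3.0, one_m2),
                    mul(a, sub(mul(one_m2, one_m2), mul(2.0, sp))))
        return mul(g, mul(sp, inner))

    return Tensor(val, (a,), (vjp,))


def _silu_d1(a) -> Tensor:
    """First derivative of silu: s(1 + x(1-s)), fused single pass."""
    a = _t(a)
    s = _expit(a.data)
    return Tensor(s * (1.0 + a.data * (1.0 - s)), (a,),
                  (lambda g: mul(g, _silu_d2(a)),))


def silu(a) -> Tensor:
    """x * sigmoid(x); d/dx = s (1 + x (1 - s)) with s = sigmoid(x)."""
    a = _t(a)
    return Tensor(a.data * _expit(a.data), (a,),
                  (lambda g: mul(g, _silu_d1(a)),))


# ---------------------------------------------------------------------------
# shape / linear algebra
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _t(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        axes = tuple(ax % a.ndim for ax in axes)
        if keepdims:
            gk = g
        else:
            sh = list(g.shape)
            for ax in sorted(axes):
                sh.insert(ax, 1)
            gk = reshape(g, tuple(sh))
        return broadcast_to(gk, a.shape)

    return Tensor(out, (a,), (vjp,))


def reshape(a, shape) -> Tensor:
    a = _t(a)
    return Tensor(a.data.reshape(shape), (a,),
                  (lambda g: reshape(g, a.shape),))


def transpose(a) -> Tensor:
    a = _t(a)
    return Tensor(a.data.T, (a,), (lambda g: transpose(g),))


def matmul(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out = a.data @ b.data

    def vjp_a(g):
        if a.ndim == 1 and b.ndim == 2:       # (k,) @ (k,m) -> (m,)
            return matmul(b, g)
        if a.ndim == 2 and b.ndim == 1:       # (n,k) @ (k,) -> (n,)
            return mul(reshape(g, (-1, 1)), reshape(b, (1, -1)))
        if a.ndim == 1 and b.ndim == 1:       # inner product
            return mul(g, b)
        return matmul(g, transpose(b))        # 2D @ 2D

    def vjp_b(g):
        if a.ndim == 1 and b.ndim == 2:
            return mul(reshape(a, (-1, 1)), reshape(g, (1, -1)))
        if a.ndim == 2 and b.ndim == 1:
            return matmul(transpose(a), g)
        if a.ndim == 1 and b.ndim == 1:
            return mul(g, a)
        return matmul(transpose(a), g)

    return Tensor(out, (a, b), (vjp_a, vjp_b))


def linear(x, w, b) -> Tensor:
    """Fused affine map x @ w + b for 2-D x; one node instead of two."""
    x, w, b = _t(x), _t(w), _t(b)
    out = x.data @ w.data + b.data
    return Tensor(out, (x, w, b),
                  (lambda g: matmul(g, transpose(w)),
                   lambda g: matmul(transpose(x), g),
                   lambda g: tsum(g, axis=0)))


def gather(a, idx) -> Tensor:
    """a[idx] for integer / slice indexing; gradient scatter-adds back."""
    a = _t(a)
    out = a.data[idx]
    return Tensor(out, (a,),
                  (lambda g: scatter_add(g, idx, a.shape),))


def scatter_add(src, idx, shape) -> Tensor:
    """zeros(shape) with ``src`` added at ``idx`` (np.add.at semantics)."""
    src = _t(src)
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, src.data)
    return Tensor(out, (src,), (lambda g: gather(g, idx),))


def concatenate(parts: Sequence, axis: int = 0) -> Tensor:
    parts = [_t(p) for p in parts]
    out = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(k):
        lo, hi = offsets[k], offsets[k + 1]

        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return gather(g, tuple(sl))

        return vjp

    return Tensor(out, tuple(parts), tuple(make_vjp(k) for k in range(len(parts))))


def where_const(mask: np.ndarray, a, b) -> Tensor:
    """Select with a *constant* boolean mask (no gradient through mask)."""
    a, b = _t(a), _t(b)
    m = np.asarray(mask, dtype=bool)
    mf = m.astype(np.float64)
    return add(mul(constant(mf), a), mul(constant(1.0 - mf), b))


def solve(A, b) -> Tensor:
    """x = A^{-1} b with implicit-function adjoint.

    For g = dL/dx:  dL/db = A^{-T} g,  dL/dA = -(A^{-T} g) x^T.
    Both are expressed with `solve` itself, so higher-order derivatives work.
    """
    A, b = _t(A), _t(b)
    x = np.linalg.solve(A.data, b.data)
    out = Tensor(x, (A, b), ())

    # the adjoint references the solution node itself so that second-order
    # chains (e.g. force-matching loss gradients) remain exact
    def vjp_A(g):
        gb = solve(transpose(A), g)
        if b.ndim == 1:
            return neg(mul(reshape(gb, (-1, 1)), reshape(out, (1, -1))))
        return neg(matmul(gb, transpose(out)))

    def vjp_b(g):
        return solve(transpose(A), g)

    out.vjps = (vjp_A, vjp_b)
    return out


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _toposort(root: Tensor) -> list:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, iter(root.parents))]
    seen.add(id(root))
    while stack:
        node, it = stack[-1]
        advanced = False
        for p in it:
            if id(p) not in seen and p.requires_grad:
                seen.add(id(p))
                stack.append((p, iter(p.parents)))
                advanced = True
                break
        if not advanced:
            order.append(node)
            stack.pop()
    return order


def grad(output: Tensor, inputs: Iterable[Tensor], grad_output=None,
         create_graph: bool = False) -> list:
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    Returns Tensors when ``create_graph`` (differentiable), detached Tensors
    otherwise. Inputs that do not influence ``output`` get zeros.
    """
    inputs = list(inputs)
    if not output.requires_grad:
        zeros = [Tensor(np.zeros(i.shape)) for i in inputs]
        return zeros
    if grad_output is None:
        grad_output = Tensor(np.ones(output.shape))
    else:
        grad_output = _t(grad_output)

    order = _toposort(output)
    grads: dict[int, Tensor] = {id(output): grad_output}
    keep: dict[int, Tensor] = {id(output): output}

    for node in reversed(order):
        g = grads.get(id(node))
        if g is None:
            continue
        for p, vjp in zip(node.parents, node.vjps):
            if not p.requires_grad:
                continue
            pg = vjp(g)
            prev = grads.get(id(p))
            grads[id(p)] = pg if prev is None else add(prev, pg)
            keep[id(p)] = p

    out = []
    for i in inputs:
        gi = grads.get(id(i))
        if gi is None:
            gi = Tensor(np.zeros(i.shape))
        if not create_graph:
            gi = gi.detach()
        out.append(gi)
    return out
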