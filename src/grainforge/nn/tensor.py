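"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is tape-based: every primitive operation records its parents
together with vector-Jacobian-product (vjp) closures.  The vjps are
themselves written in terms of primitive operations, so gradients of
gradients (needed by the critic's gradient-penalty term) come for free:
calling :func:`grad` with ``create_graph=True`` returns gradient tensors
that carry their own tape.

Only the operations required by the networks in this package are
implemented; this is not a general array library.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _sp_special

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "as_tensor",
    "grad",
    "backward",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (inference fast path)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An n-d array plus the tape metadata needed for backprop."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: "Tensor | None" = None
        self._parents: tuple = ()
        self._vjps: tuple = ()

    # -- basic introspection -------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

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

    def __pow__(self, p):
        return pow_const(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    def backward(self, gradient=None):
        backward(self, gradient)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(out_data: np.ndarray, parents: Sequence[Tensor], vjps: Sequence[Callable]) -> Tensor:
    needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(out_data, requires_grad=needs)
    if needs:
        out._parents = tuple(parents)
        out._vjps = tuple(vjps)
    return out


# ---------------------------------------------------------------------------
# graph traversal
# ---------------------------------------------------------------------------

def _topo(root: Tensor) -> list:
    order: list = []
    seen: set = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # children appear after their parents; iterate reversed


def _accumulate(root: Tensor, seed: Tensor, create_graph: bool):
    grads: dict[int, Tensor] = {id(root): seed}
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(_topo(root)):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            yield node, g
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = pg if prev is None else add(prev, pg)


def backward(root: Tensor, gradient=None) -> None:
    """Accumulate gradients into ``.grad`` of every reachable leaf."""
    if gradient is None:
        seed = Tensor(np.ones_like(root.data))
    else:
        seed = as_tensor(gradient)
    for node, g in _accumulate(root, seed, create_graph=False):
        if not node._parents:  # leaf
            node.grad = g if node.grad is None else Tensor(node.grad.data + g.data)


def grad(output: Tensor, inputs: Iterable[Tensor], grad_output=None,
         create_graph: bool = False) -> list:
    """Gradients of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors are differentiable,
    which is what the gradient-penalty term needs.
    """
    inputs = list(inputs)
    if grad_output is None:
        seed_data = np.ones_like(output.data)
    else:
        seed_data = np.asarray(grad_output.data if isinstance(grad_output, Tensor) else grad_output)
    seed = Tensor(seed_data)
    wanted = {id(t): i for i, t in enumerate(inputs)}
    results: list = [None] * len(inputs)
    for node, g in _accumulate(output, seed, create_graph=create_graph):
        i = wanted.get(id(node))
        if i is not None:
            results[i] = g if results[i] is None else add(results[i], g)
    for i, t in enumerate(inputs):
        if results[i] is None:
            results[i] = Tensor(np.zeros_like(t.data))
    return results


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reverse numpy broadcasting: reduce ``g`` down to ``shape``."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = sum_(g, axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data + b.data, (a, b),
                 (lambda g: _sum_to(g, a.shape), lambda g: _sum_to(g, b.shape)))


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, (a,), (lambda g: neg(g),))


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data - b.data, (a, b),
                 (lambda g: _sum_to(g, a.shape), lambda g: _sum_to(neg(g), b.shape)))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data * b.data, (a, b),
                 (lambda g: _sum_to(mul(g, b), a.shape),
                  lambda g: _sum_to(mul(g, a), b.shape)))


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data / b.data, (a, b),
                 (lambda g: _sum_to(div(g, b), a.shape),
                  lambda g: _sum_to(neg(div(mul(g, a), mul(b, b))), b.shape)))


def pow_const(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    return _make(a.data ** p, (a,),
                 (lambda g: mul(g, mul(Tensor(np.asarray(p, dtype=a.dtype)), pow_const(a, p - 1.0))),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    out = _make(out_data, (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, out),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), (lambda g: div(g, a),))


def sqrt(a) -> Tensor:
    return pow_const(a, 0.5)


def erf(a) -> Tensor:
    a = as_tensor(a)
    c = 2.0 / np.sqrt(np.pi)

    def vjp(g):
        return mul(g, mul(Tensor(np.asarray(c, dtype=a.dtype)), exp(neg(mul(a, a)))))

    return _make(_sp_special.erf(a.data), (a,), (vjp,))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)
    out = _make(out_data, (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, sub(Tensor(np.ones((), dtype=a.dtype)), mul(out, out))),)
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(out_data, (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, mul(out, sub(Tensor(np.ones((), dtype=a.dtype)), out))),)
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = (a.data > 0).astype(a.dtype)
    return _make(a.data * mask, (a,), (lambda g: mul(g, Tensor(mask)),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    coef = np.where(a.data > 0, 1.0, slope).astype(a.dtype)
    return _make(a.data * coef, (a,), (lambda g: mul(g, Tensor(coef)),))


_SQRT2 = float(np.sqrt(2.0))


def gelu(a) -> Tensor:
    """Exact (erf-based) GELU."""
    a = as_tensor(a)
    half = Tensor(np.asarray(0.5, dtype=a.dtype))
    one = Tensor(np.asarray(1.0, dtype=a.dtype))
    return mul(mul(half, a), add(one, erf(div(a, Tensor(np.asarray(_SQRT2, dtype=a.dtype))))))


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        gd = g
        if not keepdims and axis is not None:
            axes = axis if isinstance(axis, tuple) else (axis,)
            shape = list(a.shape)
            for ax in sorted(ax % a.ndim for ax in axes):
                shape[ax] = 1
            gd = reshape(gd, tuple(shape))
        return broadcast_to(gd, a.shape)

    return _make(out_data, (a,), (vjp,))


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.shape[ax % a.ndim]
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    if a.shape == shape:
        return a
    return _make(np.broadcast_to(a.data, shape).copy(), (a,), (lambda g: _sum_to(g, a.shape),))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return _make(a.data.reshape(shape), (a,), (lambda g: reshape(g, a.shape),))


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _make(np.ascontiguousarray(a.data.transpose(axes)), (a,),
                 (lambda g: transpose(g, inv),))


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def vjp(g):
        return scatter_like(g, a.shape, idx)

    return _make(a.data[idx], (a,), (vjp,))


def scatter_like(g, shape, idx) -> Tensor:
    """Zeros of ``shape`` with ``g`` written at ``idx`` (vjp of getitem)."""
    g = as_tensor(g)
    out_data = np.zeros(shape, dtype=g.dtype)
    np.add.at(out_data, idx, g.data)
    return _make(out_data, (g,), (lambda gg: getitem(gg, idx),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.shape[axis] for t in tensors])

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return getitem(g, tuple(sl))
        return vjp

    return _make(out_data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp_a(g):
        gb = matmul(g, _swap_last(b))
        return _sum_to(gb, a.shape)

    def vjp_b(g):
        ga = matmul(_swap_last(a), g)
        return _sum_to(ga, b.shape)

    return _make(a.data @ b.data, (a, b), (vjp_a, vjp_b))


def _swap_last(a: Tensor) -> Tensor:
    axes = list(range(a.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(a, tuple(axes))


def maximum_const(a, value: float) -> Tensor:
    a = as_tensor(a)
    mask = (a.data >= value).astype(a.dtype)
    return _make(np.maximum(a.data, value), (a,), (lambda g: mul(g, Tensor(mask)),))


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shift = np.max(a.data, axis=axis, keepdims=True)  # constant shift, gradient-free
    e = exp(sub(a, Tensor(shift)))
    return div(e, sum_(e, axis=axis, keepdims=True))


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shift = np.max(a.data, axis=axis, keepdims=True)
    s = sub(a, Tensor(shift))
    return sub(s, log(sum_(exp(s), axis=axis, keepdims=True)))
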