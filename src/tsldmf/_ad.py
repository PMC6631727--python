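"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains several small neural networks (an emitter MLP, a
mixture-density transition network, a backward GRU encoder, a combiner
MLP and a continuous-flow dynamics net).  All of them are built on the
tape-based engine in this module: a :class:`Tensor` wraps an ndarray and
records the operations applied to it; :meth:`Tensor.backward` replays the
tape in reverse topological order and accumulates gradients.

Only the primitives the model code needs are implemented.  Broadcasting
follows numpy semantics; gradients of broadcast operands are summed back
to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "softplus",
    "softplus_inv",
    "logsumexp",
    "where",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager: tensors created inside record no tape.

    Used on pure-evaluation paths (density grids, filtering facades) to
    avoid retaining every intermediate array of a large batched forward
    pass.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph.

    Parameters
    ----------
    data:
        Array value (copied to float64 view only if necessary).
    requires_grad:
        Leaf tensors with ``requires_grad=True`` receive a ``.grad``
        array after :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        if not _GRAD_ENABLED:
            _parents, _vjp, requires_grad = (), None, False
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._vjp = _vjp  # callable(upstream) -> tuple of parent grads

    # -- graph mechanics -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:  # iterative DFS post-order
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                stack_.pop()
                if node.requires_grad:
                    topo.append(node)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            _parents=(self, other),
            _vjp=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        return Tensor(
            self.data**p,
            _parents=(self,),
            _vjp=lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)

        def vjp(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:      # inner product
                return g * b, g * a
            if a.ndim == 1:                      # (k,) @ (k, n) -> (n,)
                return b @ g, np.outer(a, g)
            if b.ndim == 1:                      # (..., m, k) @ (k,) -> (..., m)
                ga = g[..., :, None] * b
                gb = np.swapaxes(a, -1, -2) @ g[..., None]
                return (_unbroadcast(ga, a.shape),
                        _unbroadcast(gb[..., 0], b.shape))
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor(self.data @ other.data, _parents=(self, other), _vjp=vjp)

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.data[idx], _parents=(self,), _vjp=vjp)

    # -- reductions / shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return Tensor(self.data.reshape(*shape), _parents=(self,),
                      _vjp=lambda g: (g.reshape(self.shape),))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities -----------------------------------------


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.log(x.data), _parents=(x,), _vjp=lambda g: (g / x.data,))


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * (1.0 - out**2),))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # numerically stable logistic
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * out * (1.0 - out),))


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), stable for large |x|; derivative is the logistic."""
    x = as_tensor(x)
    out = np.logaddexp(0.0, x.data)
    sig = 0.5 * (np.tanh(0.5 * x.data) + 1.0)
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * sig,))


def softplus_inv(y) -> np.ndarray:
    """Inverse of softplus on plain arrays (used to seed variance biases)."""
    y = np.asarray(y, dtype=np.float64)
    return y + np.log(-np.expm1(-y))


def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond)
    return Tensor(
        np.where(cond, a.data, b.data),
        _parents=(a, b),
        _vjp=lambda g: (
            _unbroadcast(np.where(cond, g, 0.0), a.shape),
            _unbroadcast(np.where(cond, 0.0, g), b.shape),
        ),
    )


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _vjp=vjp)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def vjp(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _vjp=vjp)


def transpose(x: Tensor, axes=None) -> Tensor:
    x = as_tensor(x)
    if axes is None:
        axes = tuple(range(x.ndim))[::-1]
    inverse = np.argsort(axes)
    return Tensor(np.transpose(x.data, axes), _parents=(x,),
                  _vjp=lambda g: (np.transpose(g, inverse),))


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Stable log-sum-exp along ``axis`` (used for mixture log-densities)."""
    x = as_tensor(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)  # max treated as a constant: gradient unaffected
    out = log(exp(shifted).sum(axis=axis, keepdims=True)) + Tensor(m)
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(x.shape) if i != axis % x.ndim))
    return out
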