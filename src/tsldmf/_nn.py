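"""Small neural-network building blocks on top of the autodiff engine.

Layers hold their weights as :class:`~tsldmf._ad.Tensor` leaves.  A module
exposes ``parameters()`` (for the optimizer) and ``state_dict`` /
``load_state_dict`` (for checkpoint archives).  Everything is seeded
through an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import numpy as np

from . import _ad
from ._ad import Tensor


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data.copy()
            elif isinstance(value, Module):
                state.update(value.state_dict(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                value.data = np.asarray(state[key], dtype=np.float64).copy()
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 gain: float = 1.0):
        scale = gain * np.sqrt(2.0 / (in_dim + out_dim))  # Glorot
        self.weight = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Multilayer perceptron with tanh hidden activations.

    ``hidden=()`` gives a plain affine map, which the tests use to realise
    exactly linear-Gaussian model instances.
    """

    def __init__(self, in_dim: int, hidden: tuple[int, ...], out_dim: int,
                 rng: np.random.Generator):
        sizes = (in_dim, *hidden, out_dim)
        self.layers = [Linear(sizes[i], sizes[i + 1], rng)
                       for i in range(len(sizes) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = _ad.tanh(layer(x))
        return self.layers[-1](x)


class GRUCell(Module):
    """Gated recurrent unit (single step; the encoder runs it backwards)."""

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.x2g = Linear(in_dim, 3 * hidden_dim, rng)
        self.h2g = Linear(hidden_dim, 3 * hidden_dim, rng)
        self.hidden_dim = hidden_dim

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden_dim
        gx, gh = self.x2g(x), self.h2g(h)
        r = _ad.sigmoid(gx[..., 0:H] + gh[..., 0:H])
        u = _ad.sigmoid(gx[..., H:2 * H] + gh[..., H:2 * H])
        n = _ad.tanh(gx[..., 2 * H:] + r * gh[..., 2 * H:])
        return u * h + (1.0 - u) * n


class Adam:
    """Adam optimizer (diagonal adaptive moments)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in params
                        if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total
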