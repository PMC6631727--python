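"""Backbone generative model: initial prior, transition and emitter networks.

The model assumes the 24-dim scaled observation sequence y_0..y_T is
explained by a low-dimensional (d = 2 or 3 by default) latent Markov
chain:

    p_theta(y_0:T, z_0:T) = p(z_0) p(y_0|z_0) prod_t p(y_t|z_t) p(z_t|z_{t-1})

The transition p(z_t|z_{t-1}) is a mixture-density network (K diagonal
Gaussian components whose weights, means and variances are network
outputs of z_{t-1}; K = 1 reduces to a single Gaussian).  The emitter
p(y_t|z_t) is an MLP readout, by default a diagonal Gaussian over the
scaled observation; a discretized multinomial emitter (per-feature
binning of [0, 1]) is available as an alternative family.  All variances
pass through a softplus map plus a small floor, so they are positive for
any network output.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from . import _ad
from ._ad import Tensor
from ._nn import MLP, Module
from .data import OBS_DIM

VAR_FLOOR = 1e-4
LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Plain-numpy distribution objects (evaluation-side API)
# ---------------------------------------------------------------------------


@dataclass
class LatentState:
    """Gaussian belief over the latent state at one time index."""

    mean: np.ndarray
    var: np.ndarray
    time_index: int = 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.var <= 0):
            raise ValueError("latent state variances must be positive")


@dataclass
class DiagonalGaussian:
    mean: np.ndarray
    var: np.ndarray

    def log_prob(self, x) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        ll = -0.5 * (LOG2PI + np.log(self.var) + (x - self.mean) ** 2 / self.var)
        return ll.sum(axis=-1)

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        size = self.mean.shape if n is None else (n, *self.mean.shape)
        return self.mean + np.sqrt(self.var) * rng.standard_normal(size)


@dataclass
class GaussianMixture:
    """Mixture of K diagonal Gaussians over R^d."""

    weights: np.ndarray  # (K,)
    means: np.ndarray    # (K, d)
    vars: np.ndarray     # (K, d)

    def log_prob(self, x) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        comp = -0.5 * (LOG2PI + np.log(self.vars)
                       + (x[..., None, :] - self.means) ** 2 / self.vars)
        comp = comp.sum(axis=-1) + np.log(self.weights)
        m = comp.max(axis=-1, keepdims=True)
        return (np.log(np.exp(comp - m).sum(axis=-1)) + m[..., 0])

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        count = 1 if n is None else n
        ks = rng.choice(len(self.weights), size=count, p=self.weights)
        draws = self.means[ks] + np.sqrt(self.vars[ks]) * \
            rng.standard_normal((count, self.means.shape[1]))
        return draws[0] if n is None else draws

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Moment-matched mean and diagonal variance (law of total variance)."""
        mean = self.weights @ self.means
        second = self.weights @ (self.vars + self.means**2)
        return mean, second - mean**2


@dataclass
class BinnedEmitter:
    """Per-feature multinomial over B equal bins of [0, 1]."""

    probs: np.ndarray  # (obs_dim, B)

    @property
    def n_bins(self) -> int:
        return self.probs.shape[1]

    def _bin_index(self, y: np.ndarray) -> np.ndarray:
        return np.clip((np.asarray(y) * self.n_bins).astype(int), 0, self.n_bins - 1)

    def log_prob(self, y) -> float | np.ndarray:
        idx = self._bin_index(y)
        lp = np.log(np.take_along_axis(self.probs, idx[..., None], axis=-1))[..., 0] \
            if idx.ndim > 1 else np.log(self.probs[np.arange(len(idx)), idx])
        return lp.sum(axis=-1)

    @property
    def mean(self) -> np.ndarray:
        centers = (np.arange(self.n_bins) + 0.5) / self.n_bins
        return self.probs @ centers

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(self.probs.shape[0])
        for i, p in enumerate(self.probs):
            b = rng.choice(self.n_bins, p=p)
            out[i] = (b + rng.uniform()) / self.n_bins
        return out


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


class GenerativeParams(Module):
    """All backbone parameters theta.

    Parameters
    ----------
    latent_dim:
        Dimension d of the latent space (2 or 3 in typical use).
    obs_dim:
        Observation dimension (24 for stacked IMU windows).
    mixture_K:
        Number of transition mixture components.
    hidden:
        Hidden layer widths shared by transition and emitter networks;
        ``()`` yields affine networks (exactly linear-Gaussian when K=1).
    emitter_family:
        "gaussian" (default) or "multinomial" (binned observation).
    """

    def __init__(self, latent_dim: int = 2, obs_dim: int = OBS_DIM,
                 mixture_K: int = 1, hidden: tuple[int, ...] = (32, 32),
                 emitter_family: str = "gaussian", n_bins: int = 32,
                 seed: int | np.random.Generator = 0):
        if emitter_family not in ("gaussian", "multinomial"):
            raise ValueError(f"unknown emitter family {emitter_family!r}")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.latent_dim = latent_dim
        self.obs_dim = obs_dim
        self.mixture_K = mixture_K
        self.hidden = tuple(hidden)
        self.emitter_family = emitter_family
        self.n_bins = n_bins
        K, d = mixture_K, latent_dim
        self.transition_net = MLP(d, self.hidden, K + 2 * K * d, rng)
        out = 2 * obs_dim if emitter_family == "gaussian" else obs_dim * n_bins
        self.emitter_net = MLP(d, self.hidden, out, rng)
        self.prior_mean = Tensor(np.zeros(d), requires_grad=True)
        self.prior_rawvar = Tensor(
            np.full(d, _ad.softplus_inv(1.0 - VAR_FLOOR)), requires_grad=True)

    # -- graph-side heads (Tensor in, Tensor out) -----------------------

    def transition_head(self, z: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Mixture parameters for p(z'|z): (log-weights, means, vars).

        Shapes for input (..., d): logw (..., K), means/vars (..., K, d).
        """
        K, d = self.mixture_K, self.latent_dim
        out = self.transition_net(z)
        logits = out[..., :K]
        logw = logits - _ad.logsumexp(logits, axis=-1, keepdims=True)
        means = out[..., K:K + K * d].reshape(*out.shape[:-1], K, d)
        raw = out[..., K + K * d:].reshape(*out.shape[:-1], K, d)
        return logw, means, _ad.softplus(raw) + VAR_FLOOR

    def emitter_head(self, z: Tensor) -> tuple[Tensor, Tensor]:
        """Gaussian emitter parameters (mean, var) for p(y|z)."""
        if self.emitter_family != "gaussian":
            raise ValueError("emitter_head is for the gaussian family")
        out = self.emitter_net(z)
        D = self.obs_dim
        return out[..., :D], _ad.softplus(out[..., D:]) + VAR_FLOOR

    def emitter_logits(self, z: Tensor) -> Tensor:
        """(..., obs_dim, B) log bin probabilities for the binned family."""
        out = self.emitter_net(z).reshape(*z.shape[:-1], self.obs_dim, self.n_bins)
        return out - _ad.logsumexp(out, axis=-1, keepdims=True)

    # -- serialization ---------------------------------------------------

    def config(self) -> dict:
        return {"latent_dim": self.latent_dim, "obs_dim": self.obs_dim,
                "mixture_K": self.mixture_K, "hidden": list(self.hidden),
                "emitter_family": self.emitter_family, "n_bins": self.n_bins}

    def save(self, path) -> None:
        save_archive(path, self.config(), self.state_dict())

    @classmethod
    def load(cls, path) -> "GenerativeParams":
        config, state = load_archive(path)
        obj = cls(**{**config, "hidden": tuple(config["hidden"])})
        obj.load_state_dict(state)
        return obj


def save_archive(path, config: dict, state: dict[str, np.ndarray],
                 extra_config: dict | None = None) -> None:
    """Write a parameter archive (npz with a JSON config entry)."""
    payload = dict(state)
    payload["__config__"] = np.frombuffer(
        json.dumps({**config, **(extra_config or {})}).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_archive(path) -> tuple[dict, dict[str, np.ndarray]]:
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files if k != "__config__"}
        config = json.loads(bytes(npz["__config__"].tolist()).decode())
    return config, state


# ---------------------------------------------------------------------------
# Evaluation-side operations
# ---------------------------------------------------------------------------


def initial_prior(params: GenerativeParams) -> DiagonalGaussian:
    """The diagonal-Gaussian distribution of the initial latent state z_0."""
    var = np.logaddexp(0.0, params.prior_rawvar.data) + VAR_FLOOR
    return DiagonalGaussian(params.prior_mean.data.copy(), var)


def transition_distribution(z_prev, params: GenerativeParams) -> GaussianMixture:
    """p(z_t | z_{t-1}) as a K-component diagonal-Gaussian mixture."""
    z_prev = np.asarray(z_prev, dtype=float)
    if not np.all(np.isfinite(z_prev)):
        raise ValueError("z_prev must be finite")
    logw, means, vars_ = params.transition_head(Tensor(z_prev))
    return GaussianMixture(np.exp(logw.data), means.data.copy(), vars_.data.copy())


def emitter_distribution(z, params: GenerativeParams):
    """p(y_t | z_t): diagonal Gaussian or binned multinomial over [0,1]^D."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != params.latent_dim:
        raise ValueError(f"latent dimension mismatch: {z.shape[-1]} != "
                         f"{params.latent_dim}")
    if params.emitter_family == "gaussian":
        mean, var = params.emitter_head(Tensor(z))
        return DiagonalGaussian(mean.data.copy(), var.data.copy())
    return BinnedEmitter(np.exp(params.emitter_logits(Tensor(z)).data))


def joint_log_prob(ys, zs, params: GenerativeParams) -> float:
    """log p(y_0:T, z_0:T) under the backbone model."""
    ys, zs = np.asarray(ys, dtype=float), np.asarray(zs, dtype=float)
    if len(ys) != len(zs):
        raise ValueError("observation and latent sequences differ in length")
    total = float(initial_prior(params).log_prob(zs[0]))
    total += float(emitter_distribution(zs[0], params).log_prob(ys[0]))
    for t in range(1, len(ys)):
        total += float(transition_distribution(zs[t - 1], params).log_prob(zs[t]))
        total += float(emitter_distribution(zs[t], params).log_prob(ys[t]))
    return total


def sample_trajectory(params: GenerativeParams, T: int,
                      seed: int | np.random.Generator = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral sample (z_0:T, y_0:T) from the generative model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d, D = params.latent_dim, params.obs_dim
    zs = np.empty((T + 1, d))
    ys = np.empty((T + 1, D))
    zs[0] = initial_prior(params).sample(rng)
    for t in range(T + 1):
        if t > 0:
            zs[t] = transition_distribution(zs[t - 1], params).sample(rng)
        emit = emitter_distribution(zs[t], params)
        ys[t] = emit.sample(rng)
    return zs, ys


def transition_moments(z_prev, params: GenerativeParams
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matched mean/variance of the transition mixture at ``z_prev``."""
    return transition_distribution(z_prev, params).moments()


def transition_mean_jacobian(z_prev, params: GenerativeParams) -> np.ndarray:
    """(d, d) Jacobian of the moment-matched transition mean at ``z_prev``.

    Computed by d reverse-mode sweeps; cheap because d <= 3 in practice.
    """
    z = Tensor(np.asarray(z_prev, dtype=float), requires_grad=True)
    logw, means, _ = params.transition_head(z)
    w = _ad.exp(logw)  # (K,)
    mean = (w.reshape(-1, 1) * means).sum(axis=0)  # (d,)
    d = params.latent_dim
    jac = np.empty((d, d))
    for i in range(d):
        z.zero_grad()
        for p in params.parameters():
            p.zero_grad()
        unit = np.zeros(d)
        unit[i] = 1.0
        mean.backward(unit)
        jac[i] = z.grad if z.grad is not None else 0.0
    return jac


def params_from_ssm(ssm) -> GenerativeParams:
    """Backbone parameters that realise a diagonal linear-Gaussian SSM exactly.

    Used by tests and diagnostics: affine networks (no hidden layers),
    K = 1, Gaussian emitter, with weights set so that the transition is
    N(A z, Q) and the emitter is N(C z, R).
    """
    d, D = ssm.d, ssm.obs_dim
    params = GenerativeParams(latent_dim=d, obs_dim=D, mixture_K=1, hidden=(),
                              emitter_family="gaussian", seed=0)

    def raw(var):  # softplus floor caps how small a variance can be realised
        return _ad.softplus_inv(np.maximum(var - VAR_FLOOR, 1e-12))

    trans = params.transition_net.layers[0]
    trans.weight.data[:] = 0.0
    trans.weight.data[:, 1:1 + d] = np.diag(ssm.coeffs)
    trans.bias.data[:] = 0.0
    trans.bias.data[1 + d:] = raw(ssm.process_var)
    emit = params.emitter_net.layers[0]
    emit.weight.data[:] = 0.0
    emit.weight.data[:, :D] = ssm.emission.T
    emit.bias.data[:] = 0.0
    emit.bias.data[D:] = raw(ssm.obs_var)
    params.prior_mean.data[:] = ssm.init_mean
    params.prior_rawvar.data[:] = raw(ssm.init_var)
    return params
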