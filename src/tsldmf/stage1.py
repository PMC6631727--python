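"""Stage 1: variational training of the backbone model.

The approximate posterior q_phi(z_t | y_t:T) is amortized by a gated
recurrent unit running backwards in time over the observation windows:
the GRU hidden state after consuming y_T, ..., y_t summarises exactly the
future-and-present observations, and an affine readout maps it to the
posterior mean and (softplus) variance.  Conditioning on z_{t-1} is
deliberately dropped from the encoder — interactions with the previous
latent enter only through the transition KL term of the objective —
which is known to stabilise training of deep Markov models.

Stage-1 training maximises the evidence lower bound

    ELBO = sum_t E_q[log p(y_t|z_t)]
           - KL(q(z_0) || p(z_0))
           - sum_t E_{z_{t-1}~q}[ KL(q(z_t) || p(z_t|z_{t-1})) ]

by reparameterized stochastic gradient ascent over theta and phi jointly.
The KL to the transition is analytic when the transition has a single
component and falls back to a single-sample log-ratio estimate for
mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _ad
from ._ad import Tensor
from ._nn import MLP, Adam, GRUCell, Linear, Module, clip_grad_norm
from .data import OBS_DIM, ObservationSequence
from .model import (LOG2PI, VAR_FLOOR, GenerativeParams, initial_prior,
                    load_archive, save_archive)


class TrainingError(RuntimeError):
    """Raised when optimisation produces a non-finite objective."""


class EncoderParams(Module):
    """phi: backward GRU plus affine readout to (mu_t, Sigma_t)."""

    def __init__(self, latent_dim: int = 2, obs_dim: int = OBS_DIM,
                 gru_hidden: int = 32, seed: int | np.random.Generator = 0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.latent_dim = latent_dim
        self.obs_dim = obs_dim
        self.gru_hidden = gru_hidden
        self.gru = GRUCell(obs_dim, gru_hidden, rng)
        self.readout = Linear(gru_hidden, 2 * latent_dim, rng)

    def config(self) -> dict:
        return {"latent_dim": self.latent_dim, "obs_dim": self.obs_dim,
                "gru_hidden": self.gru_hidden}

    def save(self, path) -> None:
        save_archive(path, self.config(), self.state_dict())

    @classmethod
    def load(cls, path) -> "EncoderParams":
        config, state = load_archive(path)
        obj = cls(**config)
        obj.load_state_dict(state)
        return obj


@dataclass
class PosteriorSequence:
    """Per-step diagonal-Gaussian posteriors (mu_t, Sigma_t), t = 0..T."""

    means: np.ndarray  # (T+1, d)
    vars: np.ndarray   # (T+1, d)

    def __len__(self) -> int:
        return len(self.means)


@dataclass
class ElboReport:
    """One ELBO evaluation; elbo = recon_term - kl0_term - kl_sum_term."""

    elbo: float
    recon_term: float
    kl0_term: float
    kl_sum_term: float
    n_samples: int
    seed: int


def _as_matrix(ys) -> np.ndarray:
    if isinstance(ys, ObservationSequence):
        return ys.matrix
    return np.asarray(ys, dtype=float)


def encode_graph(ys: np.ndarray, enc: EncoderParams
                 ) -> tuple[list[Tensor], list[Tensor]]:
    """Backward-recurrent posterior for a (B, T+1, D) batch, on the tape.

    Returns per-step lists of (B, d) mean and variance tensors; entry t
    depends only on y_t..y_T.
    """
    B, steps, _ = ys.shape
    d = enc.latent_dim
    h = Tensor(np.zeros((B, enc.gru_hidden)))
    mus: list[Tensor] = [None] * steps
    vars_: list[Tensor] = [None] * steps
    for t in range(steps - 1, -1, -1):
        h = enc.gru(Tensor(ys[:, t]), h)
        out = enc.readout(h)
        mus[t] = out[..., :d]
        vars_[t] = _ad.softplus(out[..., d:]) + VAR_FLOOR
    return mus, vars_


def encode(ys, enc: EncoderParams) -> PosteriorSequence:
    """q_phi(z_t | y_t:T) for every step of a single sequence."""
    mat = _as_matrix(ys)
    if mat.ndim != 2 or mat.shape[1] != enc.obs_dim:
        raise ValueError(f"expected (T+1, {enc.obs_dim}) observations")
    mus, vars_ = encode_graph(mat[None], enc)
    return PosteriorSequence(np.stack([m.data[0] for m in mus]),
                             np.stack([v.data[0] for v in vars_]))


def gaussian_kl(mu_q, var_q, mu_p, var_p) -> float:
    """Closed-form KL between diagonal Gaussians, in nats."""
    mu_q, var_q = np.asarray(mu_q, float), np.asarray(var_q, float)
    mu_p, var_p = np.asarray(mu_p, float), np.asarray(var_p, float)
    if np.any(var_q <= 0) or np.any(var_p <= 0):
        raise ValueError("variances must be positive")
    kl = 0.5 * (np.log(var_p / var_q) + (var_q + (mu_q - mu_p) ** 2) / var_p - 1.0)
    return float(kl.sum())


def _kl_graph(mu_q: Tensor, var_q: Tensor, mu_p: Tensor, var_p: Tensor) -> Tensor:
    """Graph version of the diagonal-Gaussian KL, summed over the last axis."""
    kl = 0.5 * (_ad.log(var_p) - _ad.log(var_q)
                + (var_q + (mu_q - mu_p) ** 2) / var_p - 1.0)
    return kl.sum(axis=-1)


def _gaussian_logpdf(x: Tensor, mean: Tensor, var: Tensor) -> Tensor:
    ll = -0.5 * (LOG2PI + _ad.log(var) + (x - mean) ** 2 / var)
    return ll.sum(axis=-1)


def _mixture_logpdf(z: Tensor, logw: Tensor, means: Tensor, vars_: Tensor) -> Tensor:
    """log of a diagonal-Gaussian mixture at z; shapes (...,K,d) components."""
    zb = z.reshape(*z.shape[:-1], 1, z.shape[-1])
    comp = -0.5 * (LOG2PI + _ad.log(vars_) + (zb - means) ** 2 / vars_)
    return _ad.logsumexp(comp.sum(axis=-1) + logw, axis=-1)


def elbo_graph(ys: np.ndarray, params: GenerativeParams, enc: EncoderParams,
               rng: np.random.Generator, kl_weight: float = 1.0
               ) -> tuple[Tensor, dict[str, float]]:
    """Single-sample reparameterized ELBO for a (B, T+1, D) batch.

    Returns the per-sequence mean ELBO as a graph node (for gradients)
    and a dict with the detached term values (recon, kl0, kl_sum).
    """
    B, steps, _ = ys.shape
    d = params.latent_dim
    mus, vars_ = encode_graph(ys, enc)
    eps = rng.standard_normal((steps, B, d))
    zs = [mus[t] + vars_[t] ** 0.5 * Tensor(eps[t]) for t in range(steps)]

    recon = Tensor(np.zeros(B))
    for t in range(steps):
        if params.emitter_family == "gaussian":
            mean, var = params.emitter_head(zs[t])
            recon = recon + _gaussian_logpdf(Tensor(ys[:, t]), mean, var)
        else:
            logits = params.emitter_logits(zs[t])  # (B, D, nbins)
            idx = np.clip((ys[:, t] * params.n_bins).astype(int),
                          0, params.n_bins - 1)
            b_idx = np.arange(B)[:, None], np.arange(params.obs_dim)[None, :], idx
            recon = recon + logits[b_idx].sum(axis=-1)

    prior = initial_prior(params)
    kl0 = _kl_graph(mus[0], vars_[0],
                    Tensor(np.broadcast_to(prior.mean, (B, d)).copy()),
                    Tensor(np.broadcast_to(prior.var, (B, d)).copy()))

    kl_sum = Tensor(np.zeros(B))
    for t in range(1, steps):
        logw, tmeans, tvars = params.transition_head(zs[t - 1])
        if params.mixture_K == 1:
            kl_sum = kl_sum + _kl_graph(mus[t], vars_[t],
                                        tmeans[..., 0, :], tvars[..., 0, :])
        else:
            logq = _gaussian_logpdf(zs[t], mus[t], vars_[t])
            logp = _mixture_logpdf(zs[t], logw, tmeans, tvars)
            kl_sum = kl_sum + (logq - logp)

    elbo_vec = recon - kl_weight * (kl0 + kl_sum)
    terms = {"recon": float(recon.data.mean()),
             "kl0": float(kl0.data.mean()),
             "kl_sum": float(kl_sum.data.mean())}
    return elbo_vec.mean(), terms


def elbo(ys, params: GenerativeParams, enc: EncoderParams,
         n_samples: int = 1, seed: int = 0) -> ElboReport:
    """Monte-Carlo ELBO estimate for one observation sequence."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mat = _as_matrix(ys)
    batch = np.broadcast_to(mat, (n_samples, *mat.shape)).copy()
    rng = np.random.default_rng(seed)
    _, terms = elbo_graph(batch, params, enc, rng)
    return ElboReport(elbo=terms["recon"] - terms["kl0"] - terms["kl_sum"],
                      recon_term=terms["recon"], kl0_term=terms["kl0"],
                      kl_sum_term=terms["kl_sum"], n_samples=n_samples, seed=seed)


@dataclass
class Stage1Config:
    """Training configuration for the first stage.

    ``subseq_len`` slices long recordings into fixed-length training
    subsequences so minibatches of equal-length sequences can be formed.
    """

    latent_dim: int = 2
    obs_dim: int = OBS_DIM
    mixture_K: int = 1
    hidden: tuple[int, ...] = (32, 32)
    gru_hidden: int = 32
    emitter_family: str = "gaussian"
    epochs: int = 20
    batch_size: int = 64
    lr: float = 1e-3
    subseq_len: int = 100
    kl_anneal_epochs: int = 0
    grad_clip: float = 50.0
    seed: int = 0


def slice_subsequences(dataset, length: int) -> np.ndarray:
    """Non-overlapping fixed-length slices from each sequence: (N, L, D)."""
    slices = []
    for item in dataset:
        mat = _as_matrix(item)
        n_full = len(mat) // length
        if n_full == 0 and len(mat) > 2:
            continue
        for i in range(n_full):
            slices.append(mat[i * length:(i + 1) * length])
    if not slices:
        raise TrainingError("no training subsequences could be sliced")
    return np.stack(slices)


def train_stage1(dataset, config: Stage1Config
                 ) -> tuple[GenerativeParams, EncoderParams, list[dict]]:
    """Jointly fit theta and phi by ELBO ascent.

    ``dataset`` is a list of ObservationSequence or (T+1, 24) arrays.
    Returns the trained parameters and a per-epoch log of the objective.
    """
    if not dataset:
        raise TrainingError("empty training dataset")
    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng, noise_rng = (np.random.default_rng(s)
                                        for s in ss.spawn(3))
    params = GenerativeParams(latent_dim=config.latent_dim,
                              obs_dim=config.obs_dim,
                              mixture_K=config.mixture_K,
                              hidden=config.hidden,
                              emitter_family=config.emitter_family,
                              seed=init_rng)
    enc = EncoderParams(latent_dim=config.latent_dim, obs_dim=config.obs_dim,
                        gru_hidden=config.gru_hidden, seed=init_rng)
    slices = slice_subsequences(dataset, config.subseq_len)
    opt = Adam(params.parameters() + enc.parameters(), lr=config.lr)
    log: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(len(slices))
        kl_weight = 1.0
        if config.kl_anneal_epochs > 0:
            kl_weight = min(1.0, epoch / config.kl_anneal_epochs)
        epoch_terms = {"elbo": 0.0, "recon": 0.0, "kl": 0.0}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = slices[order[start:start + config.batch_size]]
            opt.zero_grad()
            elbo_mean, terms = elbo_graph(batch, params, enc, noise_rng,
                                          kl_weight=kl_weight)
            if not np.isfinite(elbo_mean.data):
                raise TrainingError(
                    f"non-finite ELBO at epoch {epoch} (terms: {terms})")
            (-elbo_mean).backward()
            clip_grad_norm(opt.params, config.grad_clip)
            opt.step()
            epoch_terms["elbo"] += terms["recon"] - terms["kl0"] - terms["kl_sum"]
            epoch_terms["recon"] += terms["recon"]
            epoch_terms["kl"] += terms["kl0"] + terms["kl_sum"]
            n_batches += 1
        log.append({"epoch": epoch,
                    "elbo": epoch_terms["elbo"] / n_batches,
                    "recon": epoch_terms["recon"] / n_batches,
                    "kl": epoch_terms["kl"] / n_batches})
    return params, enc, log
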