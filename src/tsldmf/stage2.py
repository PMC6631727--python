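"""Stage 2: causal filtering with a learned combiner network.

The stage-1 encoder looks at future observations, so it cannot run
online.  Stage 2 replaces it with a predict-correct loop in the spirit
of the (extended) Kalman filter:

  predict:  push the previous filtered state through the frozen
            transition network; the predicted mean/variance are the
            moment-matched mixture moments at the filtered mean plus the
            first-order propagation J diag(Sigma) J^T of the filtered
            variance through the transition mean.
  correct:  a combiner MLP reads (predicted mean, log predicted variance,
            current observation y_t) and outputs an innovation correction
            to the predicted mean plus the filtered variance.

Training touches only the combiner — the transition and emitter networks
remain exactly as stage 1 left them.  The objective is the stage-1 ELBO
with the combiner-induced filtering distribution q_psi substituted for
q_phi, optionally preceded by a warm-start phase that distills the
stage-1 encoder's posterior into the causal filter (see
:func:`train_stage2`).
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _ad
from ._ad import Tensor
from ._nn import MLP, Adam, Module, clip_grad_norm
from .data import OBS_DIM, ObservationSequence
from .model import (VAR_FLOOR, GenerativeParams, LatentState, initial_prior,
                    load_archive, save_archive, transition_mean_jacobian,
                    transition_moments)
from .stage1 import (TrainingError, _as_matrix, _gaussian_logpdf, _kl_graph,
                     _mixture_logpdf, slice_subsequences)


class CombinerParams(Module):
    """psi: MLP from (pred mean, log pred variance, y_t) to the mean
    correction and filtered variance."""

    def __init__(self, latent_dim: int = 2, obs_dim: int = OBS_DIM,
                 hidden: tuple[int, ...] = (32,),
                 seed: int | np.random.Generator = 0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.latent_dim = latent_dim
        self.obs_dim = obs_dim
        self.hidden = tuple(hidden)
        self.net = MLP(2 * latent_dim + obs_dim, self.hidden, 2 * latent_dim, rng)
        # zero-init the readout: the untrained filter then reduces to a pure
        # transition rollout, which keeps early training on the latent
        # manifold where the frozen emitter is informative
        self.net.layers[-1].weight.data[:] = 0.0
        # input standardization (calibrated by train_stage2, stored with
        # the checkpoint); keeps predicted moments and observations on
        # comparable scales so the first tanh layer does not saturate
        self.in_shift = np.zeros(2 * latent_dim + obs_dim)
        self.in_scale = np.ones(2 * latent_dim + obs_dim)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.in_shift) / self.in_scale

    def config(self) -> dict:
        return {"latent_dim": self.latent_dim, "obs_dim": self.obs_dim,
                "hidden": list(self.hidden)}

    def save(self, path) -> None:
        state = self.state_dict()
        state["in_shift"] = self.in_shift
        state["in_scale"] = self.in_scale
        save_archive(path, self.config(), state)

    @classmethod
    def load(cls, path) -> "CombinerParams":
        config, state = load_archive(path)
        obj = cls(**{**config, "hidden": tuple(config["hidden"])})
        obj.in_shift = state.pop("in_shift")
        obj.in_scale = state.pop("in_scale")
        obj.load_state_dict(state)
        return obj


@dataclass
class LatentTrajectory:
    """Causally filtered latent states for one recording."""

    states: list[LatentState]
    subject_id: str = ""
    motion_label: str = "walk"

    def __len__(self) -> int:
        return len(self.states)

    @property
    def means(self) -> np.ndarray:
        return np.stack([s.mean for s in self.states])

    @property
    def vars(self) -> np.ndarray:
        return np.stack([s.var for s in self.states])

    def to_csv(self, path) -> None:
        d = self.means.shape[1]
        df = pd.DataFrame({"t": [s.time_index for s in self.states]})
        for i in range(d):
            df[f"mu{i + 1}"] = self.means[:, i]
        for i in range(d):
            df[f"var{i + 1}"] = self.vars[:, i]
        df.to_csv(path, index=False)


def predict(state: LatentState, params: GenerativeParams
            ) -> tuple[np.ndarray, np.ndarray]:
    """One-step-ahead predicted mean/variance from a filtered state.

    For a K=1 linear transition z' = a z + noise this is exactly the
    Kalman predict step: mean a mu, variance a^2 Sigma + Q.
    """
    mean, var = transition_moments(state.mean, params)
    jac = transition_mean_jacobian(state.mean, params)
    return mean, var + (jac**2) @ state.var


def combine(pred_mean, pred_var, y_t, comb: CombinerParams,
            time_index: int = 0) -> LatentState:
    """Correction step: combiner output as the filtered Gaussian state."""
    y = y_t.values if hasattr(y_t, "values") else np.asarray(y_t, dtype=float)
    pred_mean = np.asarray(pred_mean, dtype=float)
    pred_var = np.asarray(pred_var, dtype=float)
    if y.shape != (comb.obs_dim,) or pred_mean.shape != (comb.latent_dim,):
        raise ValueError("combiner input dimension mismatch")
    x = comb.standardize(np.concatenate([pred_mean, np.log(pred_var), y]))
    out = comb.net(Tensor(x))
    d = comb.latent_dim
    # Kalman-style correction: the network outputs an innovation update on
    # the predicted mean, not the state itself
    mu = pred_mean + out.data[:d]
    var = np.logaddexp(0.0, out.data[d:]) + VAR_FLOOR
    return LatentState(mean=mu, var=var, time_index=time_index)


def filter_sequence(ys, params: GenerativeParams, comb: CombinerParams,
                    subject_id: str = "", motion_label: str = "walk"
                    ) -> LatentTrajectory:
    """Run the causal predict-correct loop over a whole recording.

    The state at time t is a deterministic function of y_0..y_t only;
    the t = 0 prediction is the initial prior's moments.
    """
    mat = _as_matrix(ys)
    if len(mat) == 0:
        raise ValueError("cannot filter an empty sequence")
    if isinstance(ys, ObservationSequence):
        subject_id = subject_id or ys.subject_id
        motion_label = ys.motion_label
    prior = initial_prior(params)
    pred_mean, pred_var = prior.mean, prior.var
    states: list[LatentState] = []
    for t in range(len(mat)):
        if t > 0:
            pred_mean, pred_var = predict(states[-1], params)
        states.append(combine(pred_mean, pred_var, mat[t], comb, time_index=t))
    return LatentTrajectory(states, subject_id=subject_id,
                            motion_label=motion_label)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@contextmanager
def _frozen(params: GenerativeParams):
    """Freeze theta: no gradient is recorded for backbone parameters."""
    tensors = params.parameters()
    for p in tensors:
        p.requires_grad = False
    try:
        yield
    finally:
        for p in tensors:
            p.requires_grad = True


def _predict_batch(mu: np.ndarray, var: np.ndarray, params: GenerativeParams
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised predict step for a (B, d) batch of filtered states."""
    B, d = mu.shape
    z = Tensor(mu, requires_grad=True)
    logw, means, vars_ = params.transition_head(z)
    w = _ad.exp(logw)  # (B, K)
    mean_t = (w.reshape(B, -1, 1) * means).sum(axis=1)  # (B, d)
    second = (w.data[..., None] * (vars_.data + means.data**2)).sum(axis=1)
    mix_var = second - mean_t.data**2
    jac_sq = np.empty((B, d, d))  # jac_sq[b, i, j] = (d mean_i / d z_j)^2
    for i in range(d):
        z.zero_grad()
        unit = np.zeros((B, d))
        unit[:, i] = 1.0
        mean_t.backward(unit)
        jac_sq[:, i, :] = (z.grad if z.grad is not None else np.zeros((B, d)))**2
        z.grad = None
    pred_var = mix_var + np.einsum("bij,bj->bi", jac_sq, var)
    return mean_t.data.copy(), pred_var


def _calibrate_input_scaling(comb: CombinerParams, params: GenerativeParams,
                             pilot: np.ndarray) -> None:
    """Set the combiner's input standardization from a pure prediction
    rollout over pilot subsequences (the zero-initialized combiner adds no
    correction, so the rollout is deterministic given theta)."""
    B, steps, _ = pilot.shape
    d = params.latent_dim
    prior = initial_prior(params)
    pred_mean = np.broadcast_to(prior.mean, (B, d)).copy()
    pred_var = np.broadcast_to(prior.var, (B, d)).copy()
    base_var = np.logaddexp(0.0, 0.0) + VAR_FLOOR  # zero-init readout variance
    xs = []
    for t in range(steps):
        if t > 0:
            pred_mean, pred_var = _predict_batch(
                pred_mean, np.full((B, d), base_var), params)
        xs.append(np.concatenate([pred_mean, np.log(pred_var), pilot[:, t]],
                                 axis=1))
    stacked = np.concatenate(xs, axis=0)
    comb.in_shift = stacked.mean(axis=0)
    comb.in_scale = np.clip(stacked.std(axis=0), 0.1, None)


@dataclass
class Stage2Config:
    """Training configuration for the combiner network.

    ``warmup_epochs`` is the number of initial epochs spent distilling
    the stage-1 encoder's posterior into the combiner (only when an
    encoder is supplied to :func:`train_stage2`); ``None`` means half of
    ``epochs``.  The remaining epochs maximise the filtering ELBO.
    """

    hidden: tuple[int, ...] = (32,)
    epochs: int = 20
    batch_size: int = 64
    lr: float = 1e-3
    subseq_len: int = 100
    grad_clip: float = 50.0
    warmup_epochs: int | None = None
    seed: int = 0


def stage2_objective_graph(ys: np.ndarray, params: GenerativeParams,
                           comb: CombinerParams, rng: np.random.Generator
                           ) -> tuple[Tensor, dict[str, float]]:
    """ELBO with the filtering distribution q_psi, for a (B, L, D) batch.

    The combiner's inputs (predicted moments) are treated as constants of
    the current parameter values; gradients reach psi through each step's
    reconstruction and KL terms and through the reparameterized samples
    feeding the next transition KL.
    """
    B, steps, _ = ys.shape
    d = params.latent_dim
    prior = initial_prior(params)
    pred_mean = np.broadcast_to(prior.mean, (B, d)).copy()
    pred_var = np.broadcast_to(prior.var, (B, d)).copy()
    eps = rng.standard_normal((steps, B, d))
    recon = Tensor(np.zeros(B))
    kl = Tensor(np.zeros(B))
    z_prev: Tensor | None = None
    for t in range(steps):
        if t > 0:
            mu_prev, var_prev = z_prev_stats
            pred_mean, pred_var = _predict_batch(mu_prev, var_prev, params)
        x = comb.standardize(
            np.concatenate([pred_mean, np.log(pred_var), ys[:, t]], axis=1))
        out = comb.net(Tensor(x))
        mu_t = Tensor(pred_mean) + out[..., :d]
        var_t = _ad.softplus(out[..., d:]) + VAR_FLOOR
        z_t = mu_t + var_t ** 0.5 * Tensor(eps[t])
        mean_y, var_y = params.emitter_head(z_t)
        recon = recon + _gaussian_logpdf(Tensor(ys[:, t]), mean_y, var_y)
        if t == 0:
            kl = kl + _kl_graph(mu_t, var_t,
                                Tensor(np.broadcast_to(prior.mean, (B, d)).copy()),
                                Tensor(np.broadcast_to(prior.var, (B, d)).copy()))
        else:
            logw, tmeans, tvars = params.transition_head(z_prev)
            if params.mixture_K == 1:
                kl = kl + _kl_graph(mu_t, var_t,
                                    tmeans[..., 0, :], tvars[..., 0, :])
            else:
                logq = _gaussian_logpdf(z_t, mu_t, var_t)
                logp = _mixture_logpdf(z_t, logw, tmeans, tvars)
                kl = kl + (logq - logp)
        z_prev = z_t
        z_prev_stats = (mu_t.data.copy(), var_t.data.copy())
    elbo_vec = recon - kl
    terms = {"recon": float(recon.data.mean()), "kl": float(kl.data.mean())}
    return elbo_vec.mean(), terms


def _distill_graph(ys: np.ndarray, params: GenerativeParams,
                   comb: CombinerParams, target_mu: np.ndarray,
                   target_var: np.ndarray) -> Tensor:
    """On-policy rollout loss matching the combiner's filtered posterior
    to the stage-1 encoder's posterior (warm-start phase)."""
    B, steps, _ = ys.shape
    d = params.latent_dim
    prior = initial_prior(params)
    pred_mean = np.broadcast_to(prior.mean, (B, d)).copy()
    pred_var = np.broadcast_to(prior.var, (B, d)).copy()
    loss = Tensor(np.zeros(B))
    mu_prev = var_prev = None
    for t in range(steps):
        if t > 0:
            pred_mean, pred_var = _predict_batch(mu_prev, var_prev, params)
        x = comb.standardize(
            np.concatenate([pred_mean, np.log(pred_var), ys[:, t]], axis=1))
        out = comb.net(Tensor(x))
        mu_t = Tensor(pred_mean) + out[..., :d]
        var_t = _ad.softplus(out[..., d:]) + VAR_FLOOR
        loss = loss + ((mu_t - Tensor(target_mu[:, t])) ** 2).sum(axis=-1) \
            + ((var_t - Tensor(target_var[:, t])) ** 2).sum(axis=-1)
        mu_prev, var_prev = mu_t.data.copy(), var_t.data.copy()
    return loss.mean()


def train_stage2(dataset, params: GenerativeParams, config: Stage2Config,
                 encoder=None) -> tuple[CombinerParams, list[dict]]:
    """Fit the combiner with the backbone frozen.

    ``params`` must come from a completed stage-1 run (or be an exact
    model in oracle tests).  When the stage-1 ``encoder`` is supplied,
    the first epochs distill its smoothing posterior into the causal
    combiner along on-policy rollouts — without this warm start the
    filtering-ELBO ascent tends to stall in the saturated region of the
    frozen emitter — and the remaining epochs maximise the filtering
    ELBO itself.  Gradients never flow into theta.  Returns the trained
    combiner and a per-epoch objective log.
    """
    if params is None:
        raise TrainingError("stage 2 requires trained stage-1 parameters")
    if params.emitter_family != "gaussian":
        raise TrainingError("stage-2 training currently supports the "
                            "gaussian emitter family")
    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng, noise_rng = (np.random.default_rng(s)
                                        for s in ss.spawn(3))
    comb = CombinerParams(latent_dim=params.latent_dim, obs_dim=params.obs_dim,
                          hidden=config.hidden, seed=init_rng)
    slices = slice_subsequences(dataset, config.subseq_len)
    with _frozen(params):
        _calibrate_input_scaling(comb, params, slices[:8])
    warmup = 0
    if encoder is not None:
        warmup = (config.epochs // 2 if config.warmup_epochs is None
                  else config.warmup_epochs)
    if warmup > 0:
        from .stage1 import encode  # local import avoids a cycle
        target_mu = np.stack([encode(s, encoder).means for s in slices])
        target_var = np.stack([encode(s, encoder).vars for s in slices])
    opt = Adam(comb.parameters(), lr=config.lr)
    log: list[dict] = []
    with _frozen(params):
        for epoch in range(1, config.epochs + 1):
            order = shuffle_rng.permutation(len(slices))
            distill = epoch <= warmup
            total, n_batches = 0.0, 0
            for start in range(0, len(order), config.batch_size):
                idx = order[start:start + config.batch_size]
                batch = slices[idx]
                opt.zero_grad()
                if distill:
                    loss = _distill_graph(batch, params, comb,
                                          target_mu[idx], target_var[idx])
                    objective_value = -float(loss.data)
                else:
                    objective, terms = stage2_objective_graph(
                        batch, params, comb, noise_rng)
                    loss = -objective
                    objective_value = terms["recon"] - terms["kl"]
                if not np.isfinite(loss.data):
                    raise TrainingError(
                        f"non-finite stage-2 objective at epoch {epoch}")
                loss.backward()
                clip_grad_norm(opt.params, config.grad_clip)
                opt.step()
                total += objective_value
                n_batches += 1
            log.append({"epoch": epoch,
                        "phase": "warmup" if distill else "elbo",
                        "objective": total / n_batches})
    return comb, log
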