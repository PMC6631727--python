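"""Incremental-PCA baseline, reconstruction error, and cross-validation.

The comparison metric is the mean squared reconstruction distance over
the M test windows,

    MSE = (1/M) sum_k || x_k - x_hat_k ||^2 ,

computed in the 24-dim scaled observation space for both methods, and
summarised as the ratio MSE_IPCA / MSE_TS-LDMF (ratios above one mean
the latent-dynamics model reconstructs better than the linear baseline
at equal latent dimension).

The cross-validation harness follows the per-subject protocol: for each
subject and motion class, the k recordings are split into k consecutive
folds; each fold serves once as the test set while the other recordings
train stage 1, then stage 2; the test recording is filtered causally and
reconstructed through the emitter mean at the filtered posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import IncrementalPCA

from ._ad import Tensor
from .data import (FeatureSequence, InsufficientDataError, ObservationSequence,
                   ScalingSpec, build_observations, fit_minmax, kfold_split)
from .model import GenerativeParams
from .stage1 import Stage1Config, _as_matrix, train_stage1
from .stage2 import CombinerParams, Stage2Config, filter_sequence, train_stage2


@dataclass
class IpcaModel:
    """Incremental PCA in the 24-dim observation space (d components)."""

    components: np.ndarray  # (d, 24), orthonormal rows
    mean: np.ndarray        # (24,)
    n_components: int

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y) - self.mean) @ self.components.T

    def reconstruct(self, Y: np.ndarray) -> np.ndarray:
        return self.transform(Y) @ self.components + self.mean

    __call__ = reconstruct


def fit_ipca(train, d: int, batch_size: int = 64) -> IpcaModel:
    """Fit incremental PCA on training windows in mini-batches."""
    Y = _as_matrix(train)
    if d > Y.shape[1]:
        raise ValueError(f"cannot extract {d} components from "
                         f"{Y.shape[1]}-dim windows")
    if len(Y) < d:
        raise InsufficientDataError("fewer training windows than components")
    ipca = IncrementalPCA(n_components=d, batch_size=max(batch_size, 5 * d))
    ipca.fit(Y)
    return IpcaModel(components=ipca.components_.copy(),
                     mean=ipca.mean_.copy(), n_components=d)


@dataclass
class TsldmfReconstructor:
    """Reconstruction map: filter causally, then take the emitter mean at
    the filtered posterior mean."""

    params: GenerativeParams
    combiner: CombinerParams

    def __call__(self, Y: np.ndarray) -> np.ndarray:
        traj = filter_sequence(np.asarray(Y), self.params, self.combiner)
        mean, _ = self.params.emitter_head(Tensor(traj.means))
        return mean.data.copy()


def reconstruction_mse(test, reconstructor) -> float:
    """Mean squared reconstruction distance over the test windows."""
    Y = _as_matrix(test)
    if len(Y) == 0:
        raise InsufficientDataError("empty test set")
    residual = Y - np.asarray(reconstructor(Y))
    return float(np.mean(np.sum(residual**2, axis=1)))


def mse_ratio(test, ipca: IpcaModel, tsldmf_reconstructor) -> float:
    """MSE_IPCA / MSE_TS-LDMF on the same test windows."""
    mse_i = reconstruction_mse(test, ipca)
    mse_t = reconstruction_mse(test, tsldmf_reconstructor)
    if mse_t == 0.0:
        raise ZeroDivisionError("TS-LDMF reconstruction error is exactly zero")
    return mse_i / mse_t


@dataclass
class EvalReport:
    """One fold's comparison for one subject/motion/latent-dimension."""

    subject_id: str
    motion_label: str
    latent_dim: int
    fold_id: int
    mse_ipca: float
    mse_tsldmf: float

    @property
    def ratio(self) -> float:
        return self.mse_ipca / self.mse_tsldmf


def reports_to_frame(reports: list[EvalReport]) -> pd.DataFrame:
    rows = [{"subject": r.subject_id, "motion": r.motion_label,
             "dim": r.latent_dim, "fold": r.fold_id, "mse_ipca": r.mse_ipca,
             "mse_tsldmf": r.mse_tsldmf, "ratio": r.ratio} for r in reports]
    return pd.DataFrame(rows)


def summarize(reports: list[EvalReport]) -> pd.DataFrame:
    """Mean ratios per motion/dimension, under both aggregation orders
    (folds-then-subjects, and pooled over all folds)."""
    df = reports_to_frame(reports)
    per_subject = (df.groupby(["motion", "dim", "subject"])["ratio"].mean()
                   .groupby(["motion", "dim"]).mean()
                   .rename("ratio_subject_mean"))
    pooled = df.groupby(["motion", "dim"])["ratio"].mean().rename("ratio_pooled")
    return pd.concat([per_subject, pooled], axis=1).reset_index()


@dataclass
class CvConfig:
    """Configuration of the per-subject cross-validation harness."""

    latent_dim: int = 2
    folds: int = 5
    hidden: tuple[int, ...] = (32, 32)
    gru_hidden: int = 32
    combiner_hidden: tuple[int, ...] = (32,)
    stage1_epochs: int = 10
    stage2_epochs: int = 10
    batch_size: int = 8
    lr: float = 1e-2
    subseq_len: int = 25
    ipca_batch_size: int = 64
    seed: int = 0


def run_cross_validation(dataset: list[FeatureSequence], config: CvConfig,
                         scaling: ScalingSpec | None = None
                         ) -> list[EvalReport]:
    """Full harness: scale, window, train both stages per fold, compare.

    ``dataset`` holds raw recordings; they are grouped by (subject,
    motion) and each group needs at least ``config.folds`` recordings.
    Scaling is fitted over the entire cohort unless provided.
    """
    if scaling is None:
        scaling = fit_minmax(dataset)
    groups: dict[tuple[str, str], list[FeatureSequence]] = {}
    for seq in dataset:
        groups.setdefault((seq.subject_id, seq.motion_label), []).append(seq)
    for key, seqs in groups.items():
        if len(seqs) < config.folds:
            raise InsufficientDataError(
                f"group {key} has {len(seqs)} recordings; "
                f"{config.folds}-fold CV needs at least {config.folds}")
    master = np.random.SeedSequence(config.seed)
    reports: list[EvalReport] = []
    for (subject, motion), seqs in sorted(groups.items()):
        observations = [build_observations(s, scaling) for s in seqs]
        folds = kfold_split(len(observations), k=config.folds)
        group_seeds = master.spawn(1)[0].generate_state(2 * len(folds))
        for fold in folds:
            train_obs = [observations[i] for i in fold.train_indices]
            test_obs = [observations[i] for i in fold.test_indices]
            s1_seed = int(group_seeds[2 * (fold.fold_id - 1)] % (2**31))
            s2_seed = int(group_seeds[2 * fold.fold_id - 1] % (2**31))
            params, enc, _ = train_stage1(train_obs, Stage1Config(
                latent_dim=config.latent_dim, hidden=config.hidden,
                gru_hidden=config.gru_hidden, epochs=config.stage1_epochs,
                batch_size=config.batch_size, lr=config.lr,
                subseq_len=config.subseq_len, seed=s1_seed))
            comb, _ = train_stage2(train_obs, params, Stage2Config(
                hidden=config.combiner_hidden, epochs=config.stage2_epochs,
                batch_size=config.batch_size, lr=config.lr,
                subseq_len=config.subseq_len, seed=s2_seed), encoder=enc)
            train_windows = np.vstack([o.matrix for o in train_obs])
            ipca = fit_ipca(train_windows, config.latent_dim,
                            batch_size=config.ipca_batch_size)
            recon = TsldmfReconstructor(params, comb)
            test_windows = np.vstack([o.matrix for o in test_obs])
            reports.append(EvalReport(
                subject_id=subject, motion_label=motion,
                latent_dim=config.latent_dim, fold_id=fold.fold_id,
                mse_ipca=reconstruction_mse(test_windows, ipca),
                mse_tsldmf=reconstruction_mse(test_windows, recon)))
    return reports
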