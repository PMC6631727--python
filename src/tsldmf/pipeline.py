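"""End-to-end orchestration: simulate/load -> scale -> train -> filter ->
density -> evaluation report.

The pipeline wires the library modules together in the order a study
would run them and leaves every intermediate artifact on disk: sensor
CSVs and a manifest, the scaling envelope, per-stage checkpoints,
filtered latent-trajectory CSVs, a density model with an exported grid,
and the cross-validated comparison report.  All randomness flows from
the single master seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (FeatureSequence, build_observations, fit_minmax,
                   read_sensor_log)
from .density import DensityConfig, density_grid, fit_density, normal_region
from .evaluate import CvConfig, reports_to_frame, run_cross_validation, summarize
from .simulate import generate_cohort
from .stage1 import Stage1Config, train_stage1
from .stage2 import Stage2Config, filter_sequence, train_stage2


@dataclass
class PipelineConfig:
    """Master configuration; see the CLI docs for the YAML key names."""

    out_dir: str = "tsldmf_run"
    data_dir: str | None = None      # read existing manifest; None => simulate
    simulate: bool = True
    n_subjects: int = 2
    recordings_per_subject: int = 5
    motions: tuple[str, ...] = ("walk", "run")
    duration_s: float = 20.0
    latent_dim: int = 2
    mixture_K: int = 1
    hidden: tuple[int, ...] = (32, 32)
    gru_hidden: int = 32
    combiner_hidden: tuple[int, ...] = (32,)
    emitter_family: str = "gaussian"
    batch_size: int = 8
    stage1_epochs: int = 10
    stage2_epochs: int = 10
    lr: float = 1e-2
    subseq_len: int = 25
    folds: int = 5
    density_mass: float = 0.95
    density_iters: int = 300
    run_cv: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("motions", "hidden", "combiner_hidden"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        for key in ("motions", "hidden", "combiner_hidden"):
            payload[key] = list(payload[key])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


def write_manifest(recordings: list[FeatureSequence], data_dir: Path) -> Path:
    data_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    counters: dict[tuple[str, str], int] = {}
    for seq in recordings:
        key = (seq.subject_id, seq.motion_label)
        counters[key] = counters.get(key, 0) + 1
        name = f"{seq.subject_id}_{seq.motion_label}_{counters[key]}.csv"
        seq.to_csv(data_dir / name)
        entries.append({"file": name, "subject": seq.subject_id,
                        "motion": seq.motion_label,
                        "sampling_rate": seq.sampling_rate})
    manifest = data_dir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"recordings": entries}, fh)
    return manifest


def read_manifest(data_dir: Path) -> list[FeatureSequence]:
    manifest = Path(data_dir) / "manifest.yaml"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.yaml under {data_dir}")
    with open(manifest) as fh:
        payload = yaml.safe_load(fh)
    recordings = []
    for entry in payload["recordings"]:
        recordings.append(read_sensor_log(
            Path(data_dir) / entry["file"],
            sampling_rate=entry.get("sampling_rate", 30.0),
            subject_id=entry["subject"], motion_label=entry["motion"]))
    return recordings


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.fh = open(path, "a")

    def __call__(self, stage: str, message: str) -> None:
        line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} [{stage}] {message}"
        print(line)
        self.fh.write(line + "\n")
        self.fh.flush()


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "pipeline.log")
    config.to_yaml(out / "config.yaml")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    if config.simulate and config.data_dir is None:
        log("simulate", f"generating {config.n_subjects} subjects x "
            f"{config.recordings_per_subject} recordings x {config.motions}")
        recordings, _ = generate_cohort(
            config.n_subjects, config.recordings_per_subject,
            seed=seeds[0], motions=config.motions,
            duration_s=config.duration_s)
        write_manifest(recordings, out / "data")
    else:
        log("load", f"reading recordings from {config.data_dir}")
        recordings = read_manifest(Path(config.data_dir))

    log("scale", "fitting cohort min-max envelope")
    scaling = fit_minmax(recordings)
    scaling.to_yaml(out / "scaling.yaml")
    observations = [build_observations(seq, scaling) for seq in recordings]

    for motion in config.motions:
        motion_obs = [o for o in observations if o.motion_label == motion]
        if not motion_obs:
            continue
        log("train-stage1", f"{motion}: {len(motion_obs)} recordings")
        params, enc, s1_log = train_stage1(motion_obs, Stage1Config(
            latent_dim=config.latent_dim, mixture_K=config.mixture_K,
            hidden=config.hidden, gru_hidden=config.gru_hidden,
            emitter_family=config.emitter_family, epochs=config.stage1_epochs,
            batch_size=config.batch_size, lr=config.lr,
            subseq_len=config.subseq_len, seed=seeds[1]))
        params.save(out / f"params_{motion}.npz")
        enc.save(out / f"encoder_{motion}.npz")
        pd.DataFrame(s1_log).to_csv(out / f"stage1_log_{motion}.csv", index=False)
        log("train-stage2", f"{motion}: training combiner")
        comb, s2_log = train_stage2(motion_obs, params, Stage2Config(
            hidden=config.combiner_hidden, epochs=config.stage2_epochs,
            batch_size=config.batch_size, lr=config.lr,
            subseq_len=config.subseq_len, seed=seeds[2]), encoder=enc)
        comb.save(out / f"combiner_{motion}.npz")
        pd.DataFrame(s2_log).to_csv(out / f"stage2_log_{motion}.csv", index=False)

        log("filter", f"{motion}: filtering all recordings")
        latents_dir = out / "latents"
        latents_dir.mkdir(exist_ok=True)
        pooled = []
        counters: dict[str, int] = {}
        for obs in motion_obs:
            traj = filter_sequence(obs, params, comb)
            counters[obs.subject_id] = counters.get(obs.subject_id, 0) + 1
            traj.to_csv(latents_dir /
                        f"{obs.subject_id}_{motion}_{counters[obs.subject_id]}.csv")
            pooled.append(traj.means)
        pooled = np.vstack(pooled)

        log("density", f"{motion}: fitting latent density on "
            f"{len(pooled)} samples")
        model = fit_density(pooled, DensityConfig(iters=config.density_iters,
                                                  seed=seeds[3]))
        model.save(out / f"density_{motion}.npz")
        if config.latent_dim == 2:
            lo = pooled.min(axis=0) - 1.0
            hi = pooled.max(axis=0) + 1.0
            grid = density_grid(model, (lo[0], hi[0], lo[1], hi[1]), n=100)
            grid.to_csv(out / f"density_grid_{motion}.csv", index=False)
        region = normal_region(model, config.density_mass, seed=seeds[4])
        log("density", f"{motion}: mass {config.density_mass} threshold "
            f"{region.threshold:.6g}")

    if config.run_cv:
        log("evaluate", "running cross-validated comparison against IPCA")
        reports = run_cross_validation(recordings, CvConfig(
            latent_dim=config.latent_dim, folds=config.folds,
            hidden=config.hidden, gru_hidden=config.gru_hidden,
            combiner_hidden=config.combiner_hidden,
            stage1_epochs=config.stage1_epochs,
            stage2_epochs=config.stage2_epochs,
            batch_size=config.batch_size, lr=config.lr,
            subseq_len=config.subseq_len, seed=seeds[5]), scaling=scaling)
        reports_to_frame(reports).to_csv(out / "eval_report.csv", index=False)
        summarize(reports).to_csv(out / "eval_summary.csv", index=False)
        log("evaluate", f"mean ratio "
            f"{reports_to_frame(reports)['ratio'].mean():.3f}")
    log("done", f"artifacts in {out}")
    return out
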