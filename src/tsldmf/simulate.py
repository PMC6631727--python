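"""Synthetic smartphone-IMU gait data and linear-Gaussian test instances.

Real thigh-worn IMU recordings of walking and running are dominated by the
stride cycle: each channel is quasi-periodic at the gait fundamental
frequency with a few harmonics, sits on a gravity-dependent offset, and
carries broadband sensor/soft-tissue noise.  The generator emulates
exactly that structure: per subject it draws a fundamental frequency
(walk band 1.2-2.2 Hz, run band 2.2-3.4 Hz), three harmonic amplitudes
and phases per channel, and channel noise levels; per recording only the
noise realisation and a global phase jitter change, so repeated
recordings of one subject share their signature the way repeated laps of
a fixed course do.  Running doubles the oscillation amplitude, mirroring
the higher movement intensity that motivates the magnitude features.

The module also provides exactly-simulated linear-Gaussian state-space
instances used by the filtering tests, where closed-form Kalman results
exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureSequence

CHANNELS = ("wx", "wy", "wz", "ax", "ay", "az")
N_HARMONICS = 3
WALK_BAND = (1.2, 2.2)
RUN_BAND = (2.2, 3.4)
RUN_AMPLITUDE_FACTOR = 2.0
GRAVITY = 9.81  # m/s^2, offset on the body-frame vertical accelerometer axis

# Reference profile table for a 20-subject example cohort (gender, age in
# years, height in cm, weight in kg); used to dress synthetic subjects with
# plausible anthropometrics and by the loader tests.
REFERENCE_COHORT_ROWS: list[tuple[str, str, int, int, int]] = [
    ("subject 1", "Male", 35, 174, 62),
    ("subject 2", "Male", 25, 175, 80),
    ("subject 3", "Male", 26, 167, 56),
    ("subject 4", "Male", 28, 185, 84),
    ("subject 5", "Male", 58, 172, 64),
    ("subject 6", "Male", 37, 170, 70),
    ("subject 7", "Male", 49, 165, 85),
    ("subject 8", "Male", 28, 181, 100),
    ("subject 9", "Male", 31, 170, 80),
    ("subject 10", "Male", 59, 172, 67),
    ("subject 11", "Female", 29, 163, 58),
    ("subject 12", "Female", 47, 167, 58),
    ("subject 13", "Female", 56, 158, 63),
    ("subject 14", "Female", 36, 153, 47),
    ("subject 15", "Female", 23, 163, 55),
    ("subject 16", "Female", 22, 160, 48),
    ("subject 17", "Female", 21, 159, 54),
    ("subject 18", "Female", 21, 165, 48),
    ("subject 19", "Female", 24, 163, 68),
    ("subject 20", "Female", 22, 161, 52),
]


def load_reference_profiles() -> pd.DataFrame:
    """The bundled 20-subject reference profile table as a DataFrame."""
    return pd.DataFrame(REFERENCE_COHORT_ROWS,
                        columns=["subject", "gender", "age_yrs", "height_cm",
                                 "weight_kg"])


@dataclass
class SubjectProfile:
    """Per-subject gait signature used by the generator.

    ``fundamental_hz`` maps motion label to the stride fundamental; the
    walk value lies in 1.2-2.2 Hz and the run value in 2.2-3.4 Hz.
    Amplitudes/phases are (6 channels x 3 harmonics); ``noise_sd`` and
    ``offset`` are per channel (gyro in rad/s, accel in m/s^2).
    """

    subject_id: str
    fundamental_hz: dict[str, float]
    amplitudes: np.ndarray
    phases: np.ndarray
    noise_sd: np.ndarray
    offset: np.ndarray
    age_yrs: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None

    def __post_init__(self):
        lo_w, hi_w = WALK_BAND
        lo_r, hi_r = RUN_BAND
        if not lo_w <= self.fundamental_hz["walk"] <= hi_w:
            raise ValueError("walk fundamental outside the walking band")
        if not lo_r <= self.fundamental_hz["run"] <= hi_r:
            raise ValueError("run fundamental outside the running band")
        if not np.all(np.asarray(self.noise_sd) > 0):
            raise ValueError("noise standard deviations must be positive")


def draw_subject_profile(subject_id: str, rng: np.random.Generator,
                         reference_row: tuple | None = None) -> SubjectProfile:
    """Draw one subject's gait signature.

    Harmonic amplitudes decay geometrically (the stride fundamental
    dominates); gyro channels oscillate around zero while the body-frame
    vertical accelerometer carries the gravity offset.
    """
    fundamental = {
        "walk": float(rng.uniform(*WALK_BAND)),
        "run": float(rng.uniform(*RUN_BAND)),
    }
    base = np.concatenate([rng.uniform(0.8, 1.6, size=3),      # gyro, rad/s
                           rng.uniform(1.5, 3.0, size=3)])      # accel, m/s^2
    decay = np.array([1.0, 0.4, 0.2])
    amplitudes = base[:, None] * decay[None, :] * rng.uniform(0.8, 1.2, size=(6, 3))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(6, 3))
    noise_sd = np.array([0.1, 0.1, 0.1, 0.3, 0.3, 0.3])
    offset = np.array([0.0, 0.0, 0.0, 0.0, 0.0, GRAVITY])
    offset = offset + np.concatenate([rng.normal(0, 0.02, 3), rng.normal(0, 0.2, 3)])
    anthro = {}
    if reference_row is not None:
        _, _, age, height, weight = reference_row
        anthro = {"age_yrs": float(age), "height_cm": float(height),
                  "weight_kg": float(weight)}
    return SubjectProfile(subject_id=subject_id, fundamental_hz=fundamental,
                          amplitudes=amplitudes, phases=phases,
                          noise_sd=noise_sd, offset=offset, **anthro)


def generate_subject_sequence(profile: SubjectProfile, motion: str,
                              duration_s: float, rate: float = 30.0,
                              seed: int | np.random.Generator = 0,
                              phase_jitter: float | None = None) -> FeatureSequence:
    """Synthesize one recording for ``profile`` doing ``motion``.

    Each raw channel is a sum of three harmonics of the gait fundamental
    plus white Gaussian noise; the magnitude features are computed from
    the components, so the frame invariants hold by construction.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if motion not in ("walk", "run"):
        raise ValueError(f"unknown motion label {motion!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    f0 = profile.fundamental_hz[motion]
    amp_scale = RUN_AMPLITUDE_FACTOR if motion == "run" else 1.0
    if phase_jitter is None:
        phase_jitter = float(rng.uniform(0.0, 2.0 * np.pi))
    harmonics = np.arange(1, N_HARMONICS + 1)
    # (n, harmonics) phase argument shared across channels
    arg = 2.0 * np.pi * f0 * t[:, None] * harmonics[None, :] \
        + harmonics[None, :] * phase_jitter
    signals = np.empty((n, 6))
    for c in range(6):
        clean = (profile.amplitudes[c] * np.sin(arg + profile.phases[c])).sum(axis=1)
        signals[:, c] = profile.offset[c] + amp_scale * clean \
            + rng.normal(0.0, profile.noise_sd[c], size=n)
    return FeatureSequence.from_arrays(t, signals[:, 0:3], signals[:, 3:6],
                                       sampling_rate=rate,
                                       subject_id=profile.subject_id,
                                       motion_label=motion)


def generate_cohort(n_subjects: int, recordings_per_subject: int = 5,
                    seed: int = 0, motions: tuple[str, ...] = ("walk", "run"),
                    duration_s: float = 60.0, rate: float = 30.0,
                    ) -> tuple[list[FeatureSequence], list[SubjectProfile]]:
    """Generate a cohort: per-subject profiles drawn once, recordings that
    differ only in noise realisation and phase jitter.

    Returns the flat list of recordings (grouped by subject, then motion,
    then recording index) and the drawn profiles.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    ss = np.random.SeedSequence(seed)
    profile_rng = np.random.default_rng(ss.spawn(1)[0])
    profiles = [
        draw_subject_profile(
            f"S{i + 1:02d}", profile_rng,
            reference_row=REFERENCE_COHORT_ROWS[i % len(REFERENCE_COHORT_ROWS)])
        for i in range(n_subjects)
    ]
    recordings: list[FeatureSequence] = []
    rec_seeds = ss.spawn(n_subjects * len(motions) * recordings_per_subject)
    k = 0
    for profile in profiles:
        for motion in motions:
            for _ in range(recordings_per_subject):
                rng = np.random.default_rng(rec_seeds[k])
                k += 1
                recordings.append(generate_subject_sequence(
                    profile, motion, duration_s=duration_s, rate=rate, seed=rng))
    return recordings, profiles


@dataclass
class SsmInstance:
    """A simulated diagonal linear-Gaussian state-space model.

    z_t = A z_{t-1} + N(0, Q),  y_t = C z_t + N(0, R),  z_0 ~ N(m0, P0),
    with A = diag(coeffs) and diagonal Q, R.  ``z`` is (T+1, d) and ``y``
    is (T+1, obs_dim).
    """

    coeffs: np.ndarray          # (d,) diagonal transition coefficients
    process_var: np.ndarray     # (d,) Q diagonal
    emission: np.ndarray        # (obs_dim, d) C
    obs_var: np.ndarray         # (obs_dim,) R diagonal
    init_mean: np.ndarray       # (d,)
    init_var: np.ndarray        # (d,)
    z: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def d(self) -> int:
        return len(self.coeffs)

    @property
    def obs_dim(self) -> int:
        return self.emission.shape[0]


def simulate_from_ssm(ssm: SsmInstance, T: int,
                      seed: int | np.random.Generator = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a fresh (z, y) trajectory from an existing SSM instance."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d, D = ssm.d, ssm.obs_dim
    z = np.empty((T + 1, d))
    y = np.empty((T + 1, D))
    z[0] = ssm.init_mean + np.sqrt(ssm.init_var) * rng.standard_normal(d)
    for t in range(T + 1):
        if t > 0:
            z[t] = ssm.coeffs * z[t - 1] \
                + np.sqrt(ssm.process_var) * rng.standard_normal(d)
        y[t] = ssm.emission @ z[t] + np.sqrt(ssm.obs_var) * rng.standard_normal(D)
    return z, y


def generate_linear_gaussian_ssm(d: int, obs_dim: int, T: int, seed: int = 0,
                                 coeffs=None, process_sd: float = 0.5,
                                 obs_sd: float = 0.5) -> SsmInstance:
    """Draw and exactly simulate a stable linear-Gaussian SSM."""
    rng = np.random.default_rng(seed)
    if coeffs is None:
        coeffs = rng.uniform(0.5, 0.95, size=d) * rng.choice([-1.0, 1.0], size=d)
    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    if np.any(np.abs(coeffs) >= 1.0):
        raise ValueError("transition coefficients must satisfy |a| < 1")
    process_var = np.full(d, process_sd**2)
    obs_var = np.full(obs_dim, obs_sd**2)
    emission = rng.normal(0.0, 1.0, size=(obs_dim, d))
    init_mean = np.zeros(d)
    init_var = process_var / (1.0 - coeffs**2)  # stationary variance
    z = np.empty((T + 1, d))
    y = np.empty((T + 1, obs_dim))
    z[0] = init_mean + np.sqrt(init_var) * rng.standard_normal(d)
    for t in range(T + 1):
        if t > 0:
            z[t] = coeffs * z[t - 1] + np.sqrt(process_var) * rng.standard_normal(d)
        y[t] = emission @ z[t] + np.sqrt(obs_var) * rng.standard_normal(obs_dim)
    return SsmInstance(coeffs=coeffs, process_var=process_var, emission=emission,
                       obs_var=obs_var, init_mean=init_mean, init_var=init_var,
                       z=z, y=y)
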