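"""Sensor-log data model: feature frames, scaling, windowing, fold splits.

A smartphone IMU log is a 30 Hz stream of 3-axis angular velocity (rad/s)
and 3-axis acceleration (m/s^2).  Each time step is augmented with the two
Euclidean magnitudes (overall rotation and acceleration intensity), giving
the 8-dimensional feature frame

    x_t = (omega_x, omega_y, omega_z, omega_T, A_x, A_y, A_z, A_T).

After per-feature min-max scaling to [0, 1], the model observation stacks
the current and two previous frames,

    y_t = [x_t, x_{t-1}, x_{t-2}]   (dimension 8 x 3 = 24),

which restores approximate Markovianity of the latent dynamics at the cost
of a 16-entry overlap between consecutive windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold

FEATURE_NAMES: tuple[str, ...] = (
    "omega_x", "omega_y", "omega_z", "omega_T", "A_x", "A_y", "A_z", "A_T",
)
N_FEATURES = 8
WINDOW_STACK = 3
OBS_DIM = N_FEATURES * WINDOW_STACK  # 24

CSV_COLUMNS = ("t", "wx", "wy", "wz", "ax", "ay", "az")


class FormatError(ValueError):
    """Malformed input file (missing columns, bad header)."""


class DataError(ValueError):
    """Structurally valid input with invalid content (non-monotone time, NaN)."""


class InsufficientDataError(ValueError):
    """Too few frames/windows/recordings for the requested operation."""


def compute_magnitudes(omega_xyz, accel_xyz) -> tuple[float, float]:
    """Euclidean magnitudes of the angular-velocity and acceleration vectors."""
    omega_xyz = np.asarray(omega_xyz, dtype=float)
    accel_xyz = np.asarray(accel_xyz, dtype=float)
    if not (np.all(np.isfinite(omega_xyz)) and np.all(np.isfinite(accel_xyz))):
        raise DataError("magnitudes require finite inputs")
    return float(np.linalg.norm(omega_xyz)), float(np.linalg.norm(accel_xyz))


@dataclass(frozen=True)
class FeatureFrame:
    """One 8-dimensional sensor feature vector at a single time stamp."""

    omega_x: float
    omega_y: float
    omega_z: float
    omega_T: float
    A_x: float
    A_y: float
    A_z: float
    A_T: float
    timestamp: float

    def __post_init__(self):
        values = self.as_array()
        if not np.all(np.isfinite(values)) or not np.isfinite(self.timestamp):
            raise DataError("feature frame contains non-finite values")
        w_mag = np.linalg.norm(values[0:3])
        a_mag = np.linalg.norm(values[4:7])
        for mag, stored, name in ((w_mag, self.omega_T, "omega_T"),
                                  (a_mag, self.A_T, "A_T")):
            if abs(mag - stored) > 1e-9 * max(1.0, abs(mag)):
                raise DataError(f"{name} inconsistent with component magnitudes")

    @classmethod
    def from_components(cls, omega_xyz, accel_xyz, timestamp: float) -> "FeatureFrame":
        w_mag, a_mag = compute_magnitudes(omega_xyz, accel_xyz)
        wx, wy, wz = (float(v) for v in omega_xyz)
        ax, ay, az = (float(v) for v in accel_xyz)
        return cls(wx, wy, wz, w_mag, ax, ay, az, a_mag, float(timestamp))

    def as_array(self) -> np.ndarray:
        return np.array([self.omega_x, self.omega_y, self.omega_z, self.omega_T,
                         self.A_x, self.A_y, self.A_z, self.A_T])


@dataclass
class FeatureSequence:
    """An ordered recording of feature frames from one subject and motion."""

    frames: list[FeatureFrame]
    sampling_rate: float = 30.0
    subject_id: str = ""
    motion_label: str = "walk"

    def __post_init__(self):
        ts = np.array([f.timestamp for f in self.frames])
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise DataError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def feature_matrix(self) -> np.ndarray:
        """(n_frames, 8) array in canonical feature order."""
        return np.array([f.as_array() for f in self.frames]).reshape(-1, N_FEATURES)

    @classmethod
    def from_arrays(cls, timestamps, omega, accel, sampling_rate: float = 30.0,
                    subject_id: str = "", motion_label: str = "walk"):
        """Build from (n,) timestamps and (n, 3) angular-velocity/acceleration."""
        frames = [FeatureFrame.from_components(w, a, t)
                  for t, w, a in zip(np.asarray(timestamps),
                                     np.asarray(omega), np.asarray(accel))]
        return cls(frames, sampling_rate=sampling_rate, subject_id=subject_id,
                   motion_label=motion_label)

    def to_csv(self, path) -> None:
        mat = self.feature_matrix()
        df = pd.DataFrame({
            "t": [f.timestamp for f in self.frames],
            "wx": mat[:, 0], "wy": mat[:, 1], "wz": mat[:, 2],
            "ax": mat[:, 4], "ay": mat[:, 5], "az": mat[:, 6],
        })
        df.to_csv(path, index=False)


def read_sensor_log(path, sampling_rate: float = 30.0, subject_id: str = "",
                    motion_label: str = "walk") -> FeatureSequence:
    """Parse a comma-separated sensor log into a :class:`FeatureSequence`.

    The file must have a header row naming the columns
    ``t, wx, wy, wz, ax, ay, az`` (time in seconds, angular velocity in
    rad/s, acceleration in m/s^2).  The two magnitude features are
    computed on read, so the returned frames always satisfy the magnitude
    invariants.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse sensor log {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sensor log {path} missing columns {missing}")
    if df[list(CSV_COLUMNS)].isna().any().any():
        raise DataError(f"sensor log {path} contains missing values")
    ts = df["t"].to_numpy(dtype=float)
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise DataError(f"sensor log {path} has non-monotone timestamps")
    omega = df[["wx", "wy", "wz"]].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    return FeatureSequence.from_arrays(ts, omega, accel,
                                       sampling_rate=sampling_rate,
                                       subject_id=subject_id,
                                       motion_label=motion_label)


@dataclass
class ScalingSpec:
    """Per-feature min-max scaling envelope shared by a whole cohort."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != (N_FEATURES,) or self.maximum.shape != (N_FEATURES,):
            raise FormatError("scaling spec must cover all 8 features")
        if not np.all(self.maximum > self.minimum):
            raise DataError("degenerate scaling: max must exceed min per feature")

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Map features to [0, 1]; out-of-envelope values are clipped."""
        scaled = (np.asarray(values, dtype=float) - self.minimum) / (
            self.maximum - self.minimum)
        return np.clip(scaled, 0.0, 1.0)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * (self.maximum - self.minimum) + self.minimum

    def to_yaml(self, path) -> None:
        payload = {"features": list(FEATURE_NAMES),
                   "minimum": [float(v) for v in self.minimum],
                   "maximum": [float(v) for v in self.maximum]}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ScalingSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(np.array(payload["minimum"]), np.array(payload["maximum"]))


def fit_minmax(sequences: list[FeatureSequence]) -> ScalingSpec:
    """Elementwise min/max envelope over every frame of every sequence."""
    if not sequences or all(len(s) == 0 for s in sequences):
        raise InsufficientDataError("need at least one frame to fit scaling")
    stacked = np.vstack([s.feature_matrix() for s in sequences if len(s)])
    lo, hi = stacked.min(axis=0), stacked.max(axis=0)
    if np.any(hi <= lo):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(hi <= lo)]
        raise DataError(f"constant feature(s) {bad}: min-max scaling degenerate")
    return ScalingSpec(lo, hi)


def apply_minmax(frame: FeatureFrame, spec: ScalingSpec) -> np.ndarray:
    """Scaled 8-vector for a single frame."""
    return spec.transform(frame.as_array())


@dataclass(frozen=True)
class ObservationWindow:
    """24-dim stacked observation y_t = [x_t, x_{t-1}, x_{t-2}] (scaled)."""

    values: np.ndarray
    time_index: int

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (OBS_DIM,):
            raise FormatError(f"observation window must have dimension {OBS_DIM}")


@dataclass
class ObservationSequence:
    """Windows y_0..y_T for one recording; ``matrix`` is (T+1, 24)."""

    windows: list[ObservationWindow]
    subject_id: str = ""
    motion_label: str = "walk"

    @property
    def T(self) -> int:
        return len(self.windows) - 1

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([w.values for w in self.windows]).reshape(-1, OBS_DIM)

    def to_csv(self, path) -> None:
        cols = [f"{name}_lag{lag}" for lag in range(WINDOW_STACK)
                for name in FEATURE_NAMES]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "t", np.arange(len(self)))
        df.to_csv(path, index=False)


def build_observations(seq: FeatureSequence, spec: ScalingSpec) -> ObservationSequence:
    """Scale a recording and stack it into overlapping 24-dim windows.

    The first full window (covering raw frames 0..2) is re-indexed to
    t = 0, so an n-frame recording yields n - 2 windows.
    """
    if len(seq) < WINDOW_STACK:
        raise InsufficientDataError(
            f"windowing needs at least {WINDOW_STACK} frames, got {len(seq)}")
    scaled = spec.transform(seq.feature_matrix())
    windows = [
        ObservationWindow(np.concatenate([scaled[i], scaled[i - 1], scaled[i - 2]]), i - 2)
        for i in range(WINDOW_STACK - 1, len(seq))
    ]
    # re-index to 0..T
    windows = [ObservationWindow(w.values, t) for t, w in enumerate(windows)]
    return ObservationSequence(windows, subject_id=seq.subject_id,
                               motion_label=seq.motion_label)


@dataclass(frozen=True)
class FoldSplit:
    """One fold of a k-fold partition into consecutive blocks."""

    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray


def kfold_split(n: int, k: int = 5) -> list[FoldSplit]:
    """Split ``range(n)`` into k consecutive folds (each fold tests once).

    With n = 100 and the default k = 5 each test fold holds 20 samples,
    i.e. a 20% test share per fold.  When n is not divisible by k the
    earlier folds are one element larger.
    """
    if n < k:
        raise InsufficientDataError(f"cannot split {n} items into {k} folds")
    splitter = KFold(n_splits=k, shuffle=False)
    return [FoldSplit(fold_id=i + 1, train_indices=train, test_indices=test)
            for i, (train, test) in enumerate(splitter.split(np.arange(n)))]
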