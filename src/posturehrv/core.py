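"""Core containers shared across the pipeline.

Times are seconds since midnight of the first recording day; a recording
that crosses midnight keeps counting past 86400 so the nighttime window
(22:00-08:00) stays a single contiguous interval. All analyses operate on a
common grid of 30 s epochs anchored at the recording start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPOCH_S = 30.0

#: Body-axis convention: X positive toward the head, Y toward the subject's
#: right, Z toward the front (chest-outward). The gravity estimate is the
#: low-passed accelerometer reaction vector, which points skyward at rest, so
#: e.g. supine (back-lying) gives a gravity vector along +Z.
BODY_AXES = ("head_foot", "left_right", "front_back")

LYING_POSTURES = ("supine", "right_lateral", "left_lateral", "prone")

BEAT_LABELS = ("N", "V", "S", "A")


class FormatError(ValueError):
    """Malformed input file or configuration."""


@dataclass
class AccelSeries:
    """Triaxial chest acceleration sampled at a fixed rate.

    x, y, z are in g along the head-foot, left-right and front-back body
    axes; fs is the sampling rate in Hz (31.25 for the target device).
    """

    start_time: float
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for a in (self.x, self.y, self.z):
            if not np.all(np.isfinite(a)):
                raise ValueError("acceleration values must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.x)) / self.fs

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array of samples."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class BeatSeries:
    """Beat times (s), RR intervals (ms) and per-beat rhythm labels.

    rr_ms[k] is the interval ending at beat_time[k]; the first beat has no
    preceding interval and carries NaN. Labels follow a minimal vocabulary:
    N sinus, V ventricular ectopic, S supraventricular ectopic, A artifact.
    """

    beat_time: np.ndarray
    rr_ms: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        if not (len(self.beat_time) == len(self.rr_ms) == len(self.label)):
            raise ValueError("beat_time, rr_ms, label must have equal length")
        if len(self.beat_time) > 1 and not np.all(np.diff(self.beat_time) > 0):
            raise ValueError("beat_time must be strictly increasing")
        defined = ~np.isnan(self.rr_ms)
        if np.any(self.rr_ms[defined] <= 0):
            raise ValueError("rr_ms must be positive where defined")
        bad = set(self.label) - set(BEAT_LABELS)
        if bad:
            raise ValueError(f"unknown beat labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.beat_time)


@dataclass
class SubjectMeta:
    subject_id: str
    age: float
    sex: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError("age must be finite and non-negative")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")


@dataclass
class EpochGrid:
    """Contiguous 30 s epochs tiling a recording; partial trailing epoch dropped."""

    start_time: float
    n_epochs: int
    epoch_s: float = EPOCH_S

    @property
    def starts(self) -> np.ndarray:
        return self.start_time + self.epoch_s * np.arange(self.n_epochs)

    def index_of(self, t: np.ndarray | float) -> np.ndarray:
        """Epoch index containing time t (may fall outside [0, n_epochs))."""
        return np.floor((np.asarray(t, dtype=float) - self.start_time) / self.epoch_s).astype(int)

    @classmethod
    def for_duration(cls, start_time: float, duration_s: float, epoch_s: float = EPOCH_S) -> "EpochGrid":
        return cls(start_time, int(np.floor(duration_s / epoch_s + 1e-9)), epoch_s)

    def sample_bounds(self, fs: float) -> np.ndarray:
        """Sample index starting each epoch (plus the end sentinel) for a
        signal sampled at fs from ``start_time``. Epoch length at 31.25 Hz
        is 937.5 samples, so boundaries must be computed in time, not by a
        fixed per-epoch count, or they drift half an epoch over a night."""
        edges = self.epoch_s * np.arange(self.n_epochs + 1)
        return np.ceil(edges * fs - 1e-9).astype(int)
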