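"""Sleep-posture classification from chest-worn triaxial accelerometry.

The classifier works in four stages on a common 30 s epoch grid:

1. *movement detection* — each axis is band-pass filtered at 2-3 Hz, the
   root-sum-of-squares composite magnitude is formed, and any epoch whose
   peak magnitude reaches 20 mG is a movement epoch;
2. *gravity extraction* — each axis is low-pass filtered at 0.1 Hz
   (zero-phase), leaving the quasi-static gravitational reaction vector,
   which points skyward at rest;
3. *per-sample posture* — the angles between the gravity vector and the
   three body axes select a posture: lying when the head-foot angle is
   84 +/- 36 deg, then left lateral (< 65 deg to the left-right axis),
   right lateral (> 111 deg), supine (< 60 deg to the front-back axis) or
   prone;
4. *epoch labeling* — a non-movement epoch takes the posture held for more
   than half of its samples, otherwise it is a transition epoch.

Axis signs: X toward the head, Y toward the subject's right, Z toward the
front. This is the convention under which back-lying yields the gravity
vector along +Z (supine) and lying on the left side yields +Y (left
lateral, sky toward the subject's right).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import LYING_POSTURES, AccelSeries, EpochGrid
from .io_formats import Params

#: gravity (skyward) unit vector while perfectly holding each posture
CANONICAL_GRAVITY = {
    "supine": np.array([0.0, 0.0, 1.0]),
    "prone": np.array([0.0, 0.0, -1.0]),
    "left_lateral": np.array([0.0, 1.0, 0.0]),
    "right_lateral": np.array([0.0, -1.0, 0.0]),
    "upright": np.array([1.0, 0.0, 0.0]),
}

EPOCH_LABELS = LYING_POSTURES + ("transition", "movement", "non_lying")


def movement_flags(accel: AccelSeries, params: Params | None = None) -> np.ndarray:
    """Per-epoch movement flag: peak band-passed composite magnitude >= threshold."""
    params = params or Params()
    sos = signal.butter(params.filter_order, params.move_band_hz, btype="bandpass",
                        fs=accel.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, accel.xyz, axis=0)
    magnitude = np.sqrt(np.sum(filtered ** 2, axis=1))
    grid = EpochGrid.for_duration(accel.start_time, len(accel) / accel.fs)
    bounds = grid.sample_bounds(accel.fs)
    flags = np.empty(grid.n_epochs, dtype=bool)
    for i in range(grid.n_epochs):
        seg = magnitude[bounds[i]:bounds[i + 1]]
        flags[i] = seg.max() >= params.movement_threshold_g
    return flags


def gravity(accel: AccelSeries, params: Params | None = None) -> np.ndarray:
    """(n, 3) low-passed gravity estimate; zero-phase, so no time shift."""
    params = params or Params()
    sos = signal.butter(params.filter_order, params.gravity_corner_hz, btype="lowpass",
                        fs=accel.fs, output="sos")
    return signal.sosfiltfilt(sos, accel.xyz, axis=0)


def body_axis_angles(g_vec: np.ndarray) -> np.ndarray:
    """Angles (deg) between the gravity vector(s) and the X, Y, Z body axes."""
    g = np.atleast_2d(np.asarray(g_vec, dtype=float))
    norm = np.linalg.norm(g, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero gravity vector has no posture")
    cos = np.clip(g / norm, -1.0, 1.0)
    angles = np.degrees(np.arccos(cos))
    return angles if np.asarray(g_vec).ndim > 1 else angles[0]


def sample_posture(g_vec: np.ndarray, params: Params | None = None) -> np.ndarray | str:
    """Posture label(s) for one or many gravity vectors.

    Thresholds are applied with the strict inequalities as printed; a value
    exactly at a threshold falls through to the next clause.
    """
    params = params or Params()
    single = np.asarray(g_vec).ndim == 1
    angles = np.atleast_2d(body_axis_angles(g_vec))
    tx, ty, tz = angles[:, 0], angles[:, 1], angles[:, 2]
    lo = params.lying_center_deg - params.lying_halfwidth_deg
    hi = params.lying_center_deg + params.lying_halfwidth_deg
    lying = (tx >= lo) & (tx <= hi)

    labels = np.full(len(angles), "non_lying", dtype=object)
    left = lying & (ty < params.left_lateral_deg)
    right = lying & (ty > params.right_lateral_deg)
    rest = lying & ~left & ~right
    labels[left] = "left_lateral"
    labels[right] = "right_lateral"
    labels[rest & (tz < params.supine_deg)] = "supine"
    labels[rest & (tz >= params.supine_deg)] = "prone"
    return labels[0] if single else labels


def label_epochs(sample_labels: np.ndarray, move_flags: np.ndarray,
                 params: Params | None = None, fs: float = 31.25) -> np.ndarray:
    """Collapse per-sample labels to one label per 30 s epoch.

    Movement wins outright; otherwise the modal label must exceed the
    majority fraction of the epoch's samples or the epoch is a transition.
    """
    params = params or Params()
    n_epochs = len(move_flags)
    bounds = EpochGrid(0.0, n_epochs).sample_bounds(fs)
    out = np.empty(n_epochs, dtype=object)
    for i in range(n_epochs):
        if move_flags[i]:
            out[i] = "movement"
            continue
        seg = sample_labels[bounds[i]:bounds[i + 1]]
        values, counts = np.unique(seg.astype(str), return_counts=True)
        k = int(np.argmax(counts))
        if counts[k] > params.majority_frac * len(seg):
            out[i] = values[k]  # a dominant non_lying epoch stays non_lying
        else:
            out[i] = "transition"
    return out


def classify_postures(accel: AccelSeries, params: Params | None = None) -> dict:
    """Full chain: movement flags, gravity, per-sample posture, epoch labels.

    Returns a dict with ``labels`` (per-epoch), ``movement`` (per-epoch
    bool), ``angles`` (per-sample, degrees) and the epoch grid, so the
    intermediate quantities remain auditable.
    """
    params = params or Params()
    move = movement_flags(accel, params)
    g = gravity(accel, params)
    samples = sample_posture(g, params)
    labels = label_epochs(samples, move, params, fs=accel.fs)
    grid = EpochGrid(accel.start_time, len(labels))
    return {"labels": labels, "movement": move, "angles": body_axis_angles(g), "grid": grid}


def posture_percentages(labels: np.ndarray) -> dict[str, float]:
    """Posture shares among posture-labeled epochs only.

    Movement, transition and non_lying epochs are excluded from both the
    numerator and the denominator; the four shares sum to 100.
    """
    labels = np.asarray(labels, dtype=object)
    counts = {p: int(np.sum(labels == p)) for p in LYING_POSTURES}
    total = sum(counts.values())
    if total == 0:
        return {p: float("nan") for p in LYING_POSTURES}
    return {p: 100.0 * c / total for p, c in counts.items()}


def validate_classifier(truth: np.ndarray, predicted: np.ndarray) -> dict[str, dict[str, float]]:
    """Per-posture recall and precision of predicted against ground truth.

    Only epochs whose truth is one of the four lying postures enter the
    recall denominators; predictions may contain any epoch label (a
    transition prediction counts as a miss for its true class but a false
    positive for none). Cells with a zero denominator are NaN.
    """
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    bad = set(truth.astype(str)) - set(EPOCH_LABELS)
    if bad:
        raise ValueError(f"labels outside vocabulary: {sorted(bad)}")
    keep = np.isin(truth.astype(str), LYING_POSTURES)
    t, p = truth[keep], predicted[keep]
    out: dict[str, dict[str, float]] = {}
    for posture in LYING_POSTURES:
        tp = int(np.sum((t == posture) & (p == posture)))
        fn = int(np.sum((t == posture) & (p != posture)))
        fp = int(np.sum((t != posture) & (p == posture)))
        out[posture] = {
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
        }
    return out
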