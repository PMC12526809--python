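"""Synthetic acceleration and beat series with known ground truth.

Real overnight Holter recordings with concurrent actigraphy are not
publicly shareable, so every downstream stage is exercised against
generated data whose generating parameters are recorded as truth:

* posture schedules — piecewise-constant gravity orientation with a fixed
  random tilt per bout, white sensor noise, and 2.5 Hz oscillation bursts
  standing in for body movement (people move when turning over);
* RR series — a mean level plus sinusoidal VLF and LF components,
  respiratory sinus arrhythmia at a settable respiratory frequency with
  settable frequency jitter, optional trains of transient RR dips
  emulating the cyclic variation of heart rate seen with apnea, and
  random ectopic beats that break the normal-to-normal rule;
* whole cohorts — per-subject metadata, acceleration and beat files with
  age/sex structure, posture preferences and injected posture-specific
  heart-rate effects, for end-to-end recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from .core import LYING_POSTURES, AccelSeries, BeatSeries, EpochGrid, SubjectMeta
from .io_formats import write_accel, write_beats
from .posture import CANONICAL_GRAVITY


@dataclass
class PostureSchedule:
    """Ordered, non-overlapping posture bouts plus movement bursts."""

    intervals: list[tuple[float, float, str]]       # (start_s, duration_s, posture)
    movement_bursts: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (s0, d0, _), (s1, _, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < s0 + d0 - 1e-9:
                raise ValueError("posture intervals must be ordered and non-overlapping")
        for _, _, p in self.intervals:
            if p not in CANONICAL_GRAVITY:
                raise ValueError(f"unknown posture {p!r}")

    @property
    def start(self) -> float:
        return self.intervals[0][0]

    @property
    def end(self) -> float:
        s, d, _ = self.intervals[-1]
        return s + d


@dataclass
class RRModel:
    """Generating model for an RR-interval series.

    Band components are (amplitude ms, frequency Hz); the HF component adds
    a frequency-jitter SD controlling respiratory stability. The cvhr field
    configures dip trains: depth (ms), width (s, FWHM), within-train
    spacing (s), train start times (s) and dips per train.
    """

    mean_rr_ms: float = 1000.0
    vlf: tuple[float, float] = (0.0, 0.02)
    lf: tuple[float, float] = (0.0, 0.095)
    hf: tuple[float, float, float] = (0.0, 0.25, 0.0)   # amp, resp freq, jitter sd
    cvhr: dict | None = None    # depth_ms, width_s, inter_dip_s, train_starts, dips_per_train
    ectopic_prob: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.vlf[0] < 0 or self.lf[0] < 0 or self.hf[0] < 0:
            raise ValueError("band amplitudes must be non-negative")
        if not 0.003 <= self.vlf[1] <= 0.04:
            raise ValueError("VLF frequency outside 0.003-0.04 Hz")
        if not 0.04 <= self.lf[1] <= 0.15:
            raise ValueError("LF frequency outside 0.04-0.15 Hz")
        if not 0.15 <= self.hf[1] <= 0.40:
            raise ValueError("HF (respiratory) frequency outside 0.15-0.40 Hz")
        if not 0 <= self.ectopic_prob < 0.2:
            raise ValueError("ectopic_prob must be in [0, 0.2)")
        if self.cvhr is not None and self.cvhr["depth_ms"] >= self.mean_rr_ms:
            raise ValueError("dip depth must be smaller than the mean RR interval")

    def dip_times(self) -> np.ndarray:
        if self.cvhr is None:
            return np.empty(0)
        c = self.cvhr
        n = int(c.get("dips_per_train", 5))
        times = [t0 + k * c["inter_dip_s"] for t0 in c["train_starts"] for k in range(n)]
        return np.asarray(sorted(times))


def _jittered(vec: np.ndarray, max_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate vec by a random angle in [0, max_deg] about a random axis."""
    if max_deg == 0:
        return vec.copy()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0, max_deg))
    return Rotation.from_rotvec(axis * angle).apply(vec)


def gen_accel(schedule: PostureSchedule, noise_sd_g: float = 0.005,
              orientation_jitter_deg: float = 0.0, fs: float = 31.25,
              rng_seed: int = 0, burst_amp_g: float = 0.04,
              burst_freq_hz: float = 2.5) -> tuple[AccelSeries, np.ndarray]:
    """Acceleration for a posture schedule, plus per-epoch truth labels.

    During each bout the gravity component is the posture's canonical unit
    vector rotated once by a random tilt up to ``orientation_jitter_deg``,
    plus white noise; movement bursts superimpose a ``burst_freq_hz``
    oscillation of amplitude ``burst_amp_g``. Truth per 30 s epoch is the
    majority posture, or ``movement`` for any epoch a burst overlaps.
    """
    if orientation_jitter_deg >= 30:
        raise ValueError("orientation jitter >= 30 deg makes posture truth ambiguous")
    rng = np.random.default_rng(rng_seed)
    t0, t_end = schedule.start, schedule.end
    n = int(round((t_end - t0) * fs))
    t = t0 + np.arange(n) / fs
    xyz = np.zeros((n, 3))
    truth_sample = np.full(n, "", dtype=object)

    for s0, dur, posture in schedule.intervals:
        sel = (t >= s0 - 1e-9) & (t < s0 + dur - 1e-9)
        vec = _jittered(CANONICAL_GRAVITY[posture], orientation_jitter_deg, rng)
        xyz[sel] = vec
        truth_sample[sel] = posture if posture in LYING_POSTURES else "non_lying"

    for b0, bdur in schedule.movement_bursts:
        sel = (t >= b0) & (t < b0 + bdur)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        osc = burst_amp_g * np.sin(2 * np.pi * burst_freq_hz * t[sel])
        xyz[sel] += np.outer(osc, direction)

    xyz += rng.normal(scale=noise_sd_g, size=xyz.shape)

    grid = EpochGrid.for_duration(t0, t_end - t0)
    bounds = grid.sample_bounds(fs)
    truth = np.empty(grid.n_epochs, dtype=object)
    for i in range(grid.n_epochs):
        seg = truth_sample[bounds[i]:bounds[i + 1]]
        values, counts = np.unique(seg.astype(str), return_counts=True)
        truth[i] = values[np.argmax(counts)]
    e_start, e_end = grid.starts, grid.starts + grid.epoch_s
    for b0, bdur in schedule.movement_bursts:
        truth[(e_start < b0 + bdur) & (e_end > b0)] = "movement"

    accel = AccelSeries(start_time=t0, fs=fs, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2])
    return accel, truth


def make_validation_schedule(epochs_per_block: int = 55, blocks_per_posture: int = 4,
                             start_time: float = 0.0, burst_s: float = 40.0) -> PostureSchedule:
    """Round-robin blocks of the four lying postures with a movement burst
    straddling every posture change, for classifier validation."""
    block_s = epochs_per_block * 30.0
    order = [p for _ in range(blocks_per_posture) for p in LYING_POSTURES]
    intervals, bursts = [], []
    t = start_time
    for i, posture in enumerate(order):
        intervals.append((t, block_s, posture))
        if i > 0:
            bursts.append((t - burst_s / 2, burst_s))
        t += block_s
    return PostureSchedule(intervals=intervals, movement_bursts=bursts)


def rr_waveform(model: RRModel, t: np.ndarray, rng: np.random.Generator,
                mean_rr: np.ndarray | float | None = None) -> np.ndarray:
    """Continuous-time RR(t) in ms on the time grid t."""
    if mean_rr is None:
        mean_rr = model.mean_rr_ms
    rr = np.broadcast_to(np.asarray(mean_rr, dtype=float), t.shape).copy()
    for amp, freq in (model.vlf, model.lf):
        if amp > 0:
            rr += amp * np.sin(2 * np.pi * freq * (t - t[0]) + rng.uniform(0, 2 * np.pi))
    hf_amp, resp_f, jitter_sd = model.hf
    if hf_amp > 0:
        dt = t[1] - t[0] if len(t) > 1 else 0.5
        f_inst = np.full(len(t), resp_f)
        if jitter_sd > 0:
            # smooth random walk of the respiratory frequency, rescaled to the target SD
            raw = gaussian_filter1d(rng.normal(size=len(t)), sigma=max(4.0 / dt, 1))
            sd = raw.std()
            if sd > 0:
                f_inst = f_inst + raw / sd * jitter_sd
        phase = 2 * np.pi * np.cumsum(f_inst) * dt + rng.uniform(0, 2 * np.pi)
        rr += hf_amp * np.sin(phase)
    for tc in model.dip_times():
        sigma = model.cvhr["width_s"] / 2.355  # FWHM -> sigma
        rr -= model.cvhr["depth_ms"] * np.exp(-0.5 * ((t - tc) / sigma) ** 2)
    return rr


def gen_beats(model: RRModel, duration_s: float, start_time: float = 0.0,
              mean_rr_fn=None) -> tuple[BeatSeries, dict]:
    """Beat series from the RR model: each beat advances time by RR(t)/1000.

    ``mean_rr_fn`` optionally maps time (s) to a local mean RR (ms),
    overriding the scalar mean (used for posture-dependent heart rate).
    Returns the series and a truth record of the generating parameters.
    """
    if duration_s <= 600:
        raise ValueError("duration_s must exceed 600 s")
    rng = np.random.default_rng(model.rng_seed)
    grid_dt = 0.25
    t_grid = start_time + np.arange(int(duration_s / grid_dt) + 2) * grid_dt
    mean = mean_rr_fn(t_grid) if mean_rr_fn is not None else None
    rr_cont = rr_waveform(model, t_grid, rng, mean_rr=mean)

    times, rrs, labels = [start_time], [np.nan], ["N"]
    t = start_time
    while True:
        rr = float(np.interp(t, t_grid, rr_cont))
        if rng.uniform() < model.ectopic_prob:
            rr *= 0.7
            label = "V"
        else:
            label = "N"
        t = t + rr / 1000.0
        if t >= start_time + duration_s:
            break
        times.append(t)
        rrs.append(rr)
        labels.append(label)

    beats = BeatSeries(np.array(times), np.array(rrs), np.array(labels, dtype=object))
    truth = {
        "mean_rr_ms": model.mean_rr_ms, "vlf": model.vlf, "lf": model.lf,
        "hf": model.hf, "ectopic_prob": model.ectopic_prob,
        "dip_times": model.dip_times().tolist(),
        "cvhr": model.cvhr, "rng_seed": model.rng_seed,
    }
    return beats, truth


# ---------------------------------------------------------------------------
# cohort generation

DEFAULT_POSTURE_PREFERENCE = {
    "supine": 0.40, "right_lateral": 0.25, "left_lateral": 0.25, "prone": 0.10}


def _night_schedule(rng: np.random.Generator, preference: dict[str, float],
                    start: float, duration_s: float,
                    bout_range_s: tuple[float, float] = (1200.0, 3000.0)) -> PostureSchedule:
    """Lying bouts drawn from the preference, a short burst at each turn.

    The first four bouts visit every posture once (in random order) so each
    night samples all postures; later bouts follow the stated preference.
    """
    postures = list(preference)
    probs = np.array([preference[p] for p in postures], dtype=float)
    probs /= probs.sum()
    opening = list(rng.permutation(postures))
    intervals, bursts = [], []
    t = start
    prev = None
    while t < start + duration_s - 1e-9:
        p = opening.pop(0) if opening else rng.choice(postures, p=probs)
        dur = min(rng.uniform(*bout_range_s), start + duration_s - t)
        if prev is not None and p != prev:
            bursts.append((t - 10.0, 20.0))
        intervals.append((t, dur, p))
        prev = p
        t += dur
    return PostureSchedule(intervals=intervals, movement_bursts=bursts)


def gen_cohort(out_dir: str | Path, n_subjects: int,
               age_sex_distribution: list[tuple[float, float, str]] | None = None,
               posture_preference_by_group=None,
               index_effects: dict | None = None,
               rng_seed: int = 0,
               night_start: float = 22.25 * 3600, lying_hours: float = 5.6,
               hr_base_mean: float = 62.0, hr_base_sd: float = 3.0) -> dict:
    """Write per-subject meta/accel/beats files plus a ``truth.json`` table.

    ``age_sex_distribution`` lists (age_low, age_high, sex) strata cycled
    over subjects; ``index_effects`` may carry ``hr_offset_bpm``, a
    posture -> bpm offset added to the subject's base heart rate while in
    that posture (e.g. ``{"left_lateral": -3.0}``). Returns the truth table.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects (2 groups x 2 subjects)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)
    strata = age_sex_distribution or [(20, 59, "female"), (20, 59, "male")]
    hr_offsets = (index_effects or {}).get("hr_offset_bpm", {})
    duration_s = lying_hours * 3600.0

    truth: dict = {"rng_seed": rng_seed, "hr_offset_bpm": hr_offsets, "subjects": []}
    for i in range(n_subjects):
        lo, hi, sex = strata[i % len(strata)]
        age = float(rng.uniform(lo, hi))
        sid = f"S{i:03d}"
        meta = SubjectMeta(subject_id=sid, age=age, sex=sex)

        if callable(posture_preference_by_group):
            preference = posture_preference_by_group(meta)
        else:
            preference = posture_preference_by_group or DEFAULT_POSTURE_PREFERENCE
        schedule = _night_schedule(rng, preference, night_start, duration_s)
        accel, epoch_truth = gen_accel(
            schedule, noise_sd_g=0.005, orientation_jitter_deg=8.0,
            rng_seed=int(rng.integers(2 ** 31)))

        hr_base = rng.normal(hr_base_mean, hr_base_sd)

        def mean_rr_fn(t, _sched=schedule, _hr=hr_base):
            hr = np.full(np.shape(t), _hr, dtype=float)
            for s0, dur, posture in _sched.intervals:
                sel = (np.asarray(t) >= s0) & (np.asarray(t) < s0 + dur)
                hr[sel] = _hr + hr_offsets.get(posture, 0.0)
            return 60000.0 / hr

        model = RRModel(mean_rr_ms=60000.0 / hr_base,
                        vlf=(25.0, 0.02), lf=(25.0, 0.095), hf=(20.0, 0.25, 0.01),
                        ectopic_prob=0.02, rng_seed=int(rng.integers(2 ** 31)))
        beats, _ = gen_beats(model, duration_s, start_time=night_start,
                             mean_rr_fn=mean_rr_fn)

        write_accel(accel, out / f"{sid}_accel.csv")
        write_beats(beats, out / f"{sid}_beats.csv")
        (out / f"{sid}_meta.json").write_text(json.dumps(
            {"subject_id": sid, "age": age, "sex": sex}))
        truth["subjects"].append({
            "subject_id": sid, "age": age, "sex": sex, "hr_base": hr_base,
            "preference": preference,
            "epoch_truth": [str(x) for x in epoch_truth],
        })
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
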