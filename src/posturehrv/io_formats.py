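"""File formats, configuration and logging. No science lives here.

Formats are deliberately plain CSV so every stage of the pipeline can be
inspected with standard tools:

* acceleration: ``t,x,y,z`` — seconds, g, g, g
* beats: ``beat_time,rr_ms,label`` — seconds, milliseconds, {N,V,S,A}
* config: flat YAML key/value; unspecified keys take the defaults below
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BEAT_LABELS, AccelSeries, BeatSeries, FormatError

log = logging.getLogger("posturehrv")


# ---------------------------------------------------------------------------
# acceleration CSV

def read_accel(path: str | Path, fs: float = 31.25) -> AccelSeries:
    """Read a triaxial acceleration CSV.

    The sampling rate is inferred from the median time step and must match
    the declared ``fs`` within 1%.
    """
    df = pd.read_csv(path)
    required = {"t", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"accel CSV must have columns {sorted(required)}, got {list(df.columns)}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError("accel time column must be strictly increasing")
        fs_inferred = 1.0 / float(np.median(dt))
        if abs(fs_inferred - fs) / fs > 0.01:
            raise FormatError(f"inferred rate {fs_inferred:.3f} Hz does not match declared {fs} Hz")
    return AccelSeries(start_time=float(t[0]), fs=fs,
                       x=df["x"].to_numpy(float), y=df["y"].to_numpy(float), z=df["z"].to_numpy(float))


def write_accel(accel: AccelSeries, path: str | Path) -> None:
    pd.DataFrame({"t": accel.times, "x": accel.x, "y": accel.y, "z": accel.z}).to_csv(
        path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# beats CSV

def read_beats(path: str | Path) -> BeatSeries:
    df = pd.read_csv(path)
    required = {"beat_time", "rr_ms", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"beats CSV must have columns {sorted(required)}, got {list(df.columns)}")
    labels = df["label"].astype(str).to_numpy()
    bad = set(labels) - set(BEAT_LABELS)
    if bad:
        raise FormatError(f"unknown beat labels: {sorted(bad)}")
    rr = df["rr_ms"].to_numpy(dtype=float)
    if np.any(rr[~np.isnan(rr)] <= 0):
        raise FormatError("rr_ms must be positive where defined")
    try:
        return BeatSeries(beat_time=df["beat_time"].to_numpy(float), rr_ms=rr, label=labels)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    # 17 significant digits so RR values survive the round trip bit-exactly
    pd.DataFrame({"beat_time": beats.beat_time, "rr_ms": beats.rr_ms,
                  "label": beats.label}).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class Params:
    """Every tunable threshold of the pipeline, with the published defaults.

    Angles are degrees, times seconds, accelerations g, RR intervals ms.
    """

    # posture classification
    movement_threshold_g: float = 0.020     # peak 2-3 Hz band-passed magnitude
    move_band_hz: tuple[float, float] = (2.0, 3.0)
    gravity_corner_hz: float = 0.1
    filter_order: int = 4
    lying_center_deg: float = 84.0
    lying_halfwidth_deg: float = 36.0
    left_lateral_deg: float = 65.0          # head-foot angle window for "lying"
    right_lateral_deg: float = 111.0
    supine_deg: float = 60.0
    majority_frac: float = 0.5              # >50% of samples defines the epoch posture

    # frequency bands (Hz)
    vlf_band: tuple[float, float] = (0.003, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)

    # HRV
    resample_hz: float = 2.0
    min_nn_per_epoch: int = 10
    max_gap_s: float = 5.0                  # spline bridges gaps up to this span
    lfhf_convention: str = "power"          # "power" (squared amplitude ratio) or "amplitude"
    hsi_window_s: float = 256.0             # 512 points at 2 Hz
    hsi_halfwidth_bins: int = 5             # peak +/- W bins (~ +/-0.0195 Hz)

    # CVHR detector
    cvhr_baseline_window_s: float = 130.0
    cvhr_depth_min_ms: float = 50.0
    cvhr_width_s: tuple[float, float] = (10.0, 120.0)
    cvhr_inter_dip_s: tuple[float, float] = (25.0, 130.0)
    cvhr_interval_ratio: tuple[float, float] = (0.5, 2.0)
    ahi_severity_cutoff: float = 15.0       # /h; >= is moderate-to-severe

    # eligibility / aggregation
    night_window: tuple[float, float] = (22 * 3600.0, 32 * 3600.0)  # 22:00-08:00(+1d)
    min_lying_hours: float = 5.0
    min_sinus_frac: float = 0.80
    sinus_rule: str = "beats"               # "beats" (beat-count fraction) or "time"
    min_epochs_per_posture: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.left_lateral_deg < self.right_lateral_deg < 180:
            raise ValueError("require 0 < left_lateral_deg < right_lateral_deg < 180")
        if not 0 < self.supine_deg < 90:
            raise ValueError("require 0 < supine_deg < 90")
        if self.lfhf_convention not in ("power", "amplitude"):
            raise ValueError("lfhf_convention must be 'power' or 'amplitude'")
        if self.sinus_rule not in ("beats", "time"):
            raise ValueError("sinus_rule must be 'beats' or 'time'")

    def replace(self, **kw) -> "Params":
        return dataclasses.replace(self, **kw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None) -> Params:
    """Load parameters from a flat YAML file; unknown keys are an error."""
    if path is None:
        return Params()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a key/value mapping")
    known = {f.name: f for f in dataclasses.fields(Params)}
    unknown = set(raw) - set(known)
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return Params(**coerced)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid config: {exc}") from exc


def log_params(params: Params, stage: str) -> None:
    """One log line per pipeline stage echoing the effective parameters."""
    log.info("%s params: %s", stage, params.as_dict())
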