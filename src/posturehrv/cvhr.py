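"""Cyclic variation in heart rate (CVHR) and apnea screening.

Obstructive apnea episodes leave a signature in the RR series: transient
heart-rate accelerations (RR dips) recurring with the apnea cycle, roughly
every half minute to two minutes. The detector here finds candidate dips
as local minima of the 2 Hz-resampled NN series relative to a moving-median
baseline, keeps those deep and wide enough, and then requires cyclicity: a
dip only counts as CVHR if it belongs to a train of at least three dips
with regular spacing. Dips per hour of lying posture estimate the
apnea-hypopnea index (AHI); 15/h or more marks moderate-to-severe apnea.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import LYING_POSTURES, EpochGrid
from .hrv import NNSeries, Resampled2Hz, resample_2hz
from .io_formats import Params


@dataclass
class DipEvent:
    nadir_time: float
    depth_ms: float
    width_s: float
    member_of_train: bool = False


@dataclass
class ApneaScreen:
    dips_per_hour: float
    severity: str                 # normal_to_mild | moderate_to_severe
    epoch_positive: np.ndarray    # per-epoch bool
    dips: list                    # train-member DipEvents inside lying epochs


def _baseline(rr: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    w = int(round(window_s * rate)) | 1  # odd window
    return pd.Series(rr).rolling(w, center=True, min_periods=1).median().to_numpy()


def detect_dips(nn: NNSeries, params: Params | None = None,
                series: Resampled2Hz | None = None) -> list[DipEvent]:
    """Find RR dips: local minima below a moving-median baseline.

    A dip qualifies when its depth (baseline minus RR at the nadir) reaches
    ``cvhr_depth_min_ms`` and its full width at half depth lies within
    ``cvhr_width_s``.
    """
    params = params or Params()
    if series is None:
        series = resample_2hz(nn, params=params)
    rr = series.rr_ms
    base = _baseline(rr, series.rate, params.cvhr_baseline_window_s)
    deficit = base - rr  # positive where RR dips below baseline
    w_lo, w_hi = params.cvhr_width_s
    peaks, props = signal.find_peaks(
        deficit,
        height=params.cvhr_depth_min_ms,
        width=(w_lo * series.rate, w_hi * series.rate),
        rel_height=0.5,
    )
    times = series.times
    dips = []
    for i, p in enumerate(peaks):
        if not series.valid[p]:
            continue
        # the sloping baseline near a train edge skews the deficit maximum;
        # the nadir is the raw RR minimum in the dip's neighborhood
        half = int(props["widths"][i] / 2)
        a, b = max(p - half, 0), min(p + half + 1, len(rr))
        nadir = a + int(np.argmin(rr[a:b]))
        dips.append(DipEvent(nadir_time=float(times[nadir]),
                             depth_ms=float(props["peak_heights"][i]),
                             width_s=float(props["widths"][i] / series.rate)))
    return dips


def cluster_trains(dips: list[DipEvent], params: Params | None = None) -> list[DipEvent]:
    """Mark dips that belong to a cyclic train.

    A train is a maximal run of dips whose consecutive spacings all fall in
    ``cvhr_inter_dip_s`` and whose neighboring spacings keep a ratio within
    ``cvhr_interval_ratio``. Only runs of three or more dips (a dip with at
    least two companions) are trains.
    """
    params = params or Params()
    lo, hi = params.cvhr_inter_dip_s
    r_lo, r_hi = params.cvhr_interval_ratio
    for d in dips:
        d.member_of_train = False
    times = np.array([d.nadir_time for d in dips])
    order = np.argsort(times)
    run: list[int] = []
    prev_gap: float | None = None

    def close(run: list[int]) -> None:
        if len(run) >= 3:
            for j in run:
                dips[j].member_of_train = True

    for i in order:
        if not run:
            run, prev_gap = [i], None
            continue
        gap = times[i] - times[run[-1]]
        ok = lo <= gap <= hi and (prev_gap is None or r_lo <= gap / prev_gap <= r_hi)
        if ok:
            run.append(i)
            prev_gap = gap
        else:
            close(run)
            # the previous dip may seed a new train with the current one
            if lo <= gap <= hi:
                run, prev_gap = [run[-1], i], gap
            else:
                run, prev_gap = [i], None
    close(run)
    return dips


def screen(nn: NNSeries, epoch_labels: np.ndarray, grid: EpochGrid,
           params: Params | None = None, series: Resampled2Hz | None = None) -> ApneaScreen:
    """Estimate AHI and classify apnea severity from CVHR in lying epochs.

    AHI = train-member dips with nadir inside a lying epoch, per hour of
    lying epochs; an epoch is apnea-positive when at least one such nadir
    falls inside it. Severity is moderate-to-severe at AHI >= 15/h.
    """
    params = params or Params()
    dips = cluster_trains(detect_dips(nn, params, series=series), params)
    labels = np.asarray(epoch_labels, dtype=object)
    lying = np.isin(labels.astype(str), LYING_POSTURES)
    lying_seconds = lying.sum() * grid.epoch_s
    positive = np.zeros(grid.n_epochs, dtype=bool)
    counted = []
    for d in dips:
        if not d.member_of_train:
            continue
        e = int(grid.index_of(d.nadir_time))
        if 0 <= e < grid.n_epochs and lying[e]:
            positive[e] = True
            counted.append(d)
    if lying_seconds == 0:
        return ApneaScreen(float("nan"), "undefined", positive, counted)
    ahi = len(counted) * 3600.0 / lying_seconds  # exact at round-number boundaries
    severity = ("moderate_to_severe" if ahi >= params.ahi_severity_cutoff
                else "normal_to_mild")
    return ApneaScreen(ahi, severity, positive, counted)
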