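"""Heart rate variability indices on the 30 s epoch grid.

Time-domain indices (HR, SDRR) are computed per epoch from normal-to-normal
(NN) intervals only. Frequency-domain indices come from complex
demodulation of the NN tachogram resampled at 2 Hz: for each band (VLF
0.003-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz) the series is multiplied
by a complex exponential at the band center and low-pass filtered at half
the bandwidth, yielding time-resolved band amplitude (ms) and instantaneous
frequency (Hz) at 2 Hz resolution. The HF spectral power concentration
index (Hsi) measures how much HF power sits within a few FFT bins of the
HF spectral peak — a proxy for respiratory-frequency stability.

Amplitude convention: amp(t) = 2 |y_lp(t)|, so a pure sinusoid of peak
amplitude A ms returns A. LF/HF defaults to the squared amplitude ratio
(power convention); the plain amplitude ratio is available via config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .core import BeatSeries, EpochGrid
from .io_formats import Params

BANDS = ("VLF", "LF", "HF")


@dataclass
class NNSeries:
    """Times (s) and values (ms) of normal-to-normal intervals only."""

    times: np.ndarray   # terminating beat time of each kept interval
    rr_ms: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Resampled2Hz:
    """NN tachogram on a uniform 0.5 s grid with a validity mask."""

    t0: float
    rate: float
    rr_ms: np.ndarray
    valid: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.rr_ms)) / self.rate


@dataclass
class BandDemod:
    band: str
    f0: float
    amp_ms: np.ndarray
    inst_freq_hz: np.ndarray


def extract_nn(beats: BeatSeries) -> NNSeries:
    """Keep interval k only when beats k-1 and k are both sinus (N)."""
    if len(beats) < 2:
        return NNSeries(np.empty(0), np.empty(0))
    is_n = beats.label == "N"
    keep = is_n[1:] & is_n[:-1] & ~np.isnan(beats.rr_ms[1:])
    return NNSeries(beats.beat_time[1:][keep], beats.rr_ms[1:][keep])


def epoch_hr_sdrr(nn: NNSeries, grid: EpochGrid, params: Params | None = None) -> pd.DataFrame:
    """HR (bpm) and SDRR (ms, n-1 denominator) per epoch.

    Epochs with fewer than ``min_nn_per_epoch`` NN intervals get NaN.
    """
    params = params or Params()
    idx = grid.index_of(nn.times)
    hr = np.full(grid.n_epochs, np.nan)
    sdrr = np.full(grid.n_epochs, np.nan)
    inside = (idx >= 0) & (idx < grid.n_epochs)
    for e in np.unique(idx[inside]):
        vals = nn.rr_ms[idx == e]
        if len(vals) >= params.min_nn_per_epoch:
            hr[e] = 60000.0 / vals.mean()
            sdrr[e] = vals.std(ddof=1)
    return pd.DataFrame({"epoch_index": np.arange(grid.n_epochs), "hr": hr, "sdrr": sdrr})


def resample_2hz(nn: NNSeries, start_time: float | None = None,
                 duration_s: float | None = None, params: Params | None = None) -> Resampled2Hz:
    """Cubic-spline interpolation of the NN tachogram onto a 2 Hz grid.

    Samples outside the NN support, or inside annotation gaps longer than
    ``max_gap_s``, are marked invalid (the spline still bridges short gaps).
    """
    params = params or Params()
    if len(nn) < 4:
        raise ValueError("need at least 4 NN intervals for cubic-spline resampling")
    t0 = nn.times[0] if start_time is None else start_time
    t_end = nn.times[-1] if duration_s is None else t0 + duration_s
    n = max(int(np.floor((t_end - t0) * params.resample_hz)) + 1, 1)
    grid_t = t0 + np.arange(n) / params.resample_hz
    spline = CubicSpline(nn.times, nn.rr_ms)
    rr = spline(grid_t)

    valid = (grid_t >= nn.times[0]) & (grid_t <= nn.times[-1])
    gaps = np.diff(nn.times)
    for g in np.nonzero(gaps > params.max_gap_s)[0]:
        valid &= ~((grid_t > nn.times[g]) & (grid_t < nn.times[g + 1]))
    return Resampled2Hz(t0=t0, rate=params.resample_hz, rr_ms=rr, valid=valid)


def band_edges(band: str, params: Params) -> tuple[float, float]:
    try:
        return {"VLF": params.vlf_band, "LF": params.lf_band, "HF": params.hf_band}[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of {BANDS}") from None


def complex_demodulate(series: Resampled2Hz, band: str, params: Params | None = None) -> BandDemod:
    """Band amplitude and instantaneous frequency by complex demodulation.

    The (mean-removed) series is multiplied by exp(-i 2 pi f0 t) with f0 the
    arithmetic band center, then low-pass filtered at half the bandwidth
    (zero-phase Butterworth). amp = 2 |y|; the instantaneous frequency is
    f0 plus the unwrapped-phase derivative, clamped to the band; where the
    amplitude vanishes the frequency is reported as f0.
    """
    params = params or Params()
    lo, hi = band_edges(band, params)
    f0 = 0.5 * (lo + hi)
    cutoff = 0.5 * (hi - lo)
    t = series.times - series.t0
    x = series.rr_ms.astype(float).copy()
    if series.valid.any():
        x[~series.valid] = x[series.valid].mean()
        x = x - x[series.valid].mean()
    else:
        x = x - x.mean()
    y = x * np.exp(-2j * np.pi * f0 * t)
    sos = signal.butter(params.filter_order, cutoff, btype="lowpass",
                        fs=series.rate, output="sos")
    y_lp = signal.sosfiltfilt(sos, y)
    amp = 2.0 * np.abs(y_lp)

    phase = np.unwrap(np.angle(y_lp))
    dt = 1.0 / series.rate
    inst = f0 + np.gradient(phase, dt) / (2.0 * np.pi)
    inst = np.clip(inst, lo, hi)
    inst[amp <= 1e-12] = f0
    return BandDemod(band=band, f0=f0, amp_ms=amp, inst_freq_hz=inst)


def epoch_band_stats(demods: dict[str, BandDemod], series: Resampled2Hz,
                     grid: EpochGrid, params: Params | None = None) -> pd.DataFrame:
    """Per-epoch band amplitudes, HF frequency and LF/HF.

    Amplitudes are plain means over the epoch's 2 Hz samples; instantaneous
    frequency is amplitude-weighted. Epochs overlapping invalid samples are
    NaN throughout; LF/HF is NaN when the HF amplitude is zero.
    """
    params = params or Params()
    idx = grid.index_of(series.times)
    inside = (idx >= 0) & (idx < grid.n_epochs)
    out = pd.DataFrame({"epoch_index": np.arange(grid.n_epochs)})
    for band in BANDS:
        out[band.lower() + "_amp"] = np.nan
    out["hf_freq"] = np.nan
    out["lf_hf"] = np.nan

    for e in range(grid.n_epochs):
        sel = inside & (idx == e)
        if not sel.any() or not series.valid[sel].all():
            continue
        for band in BANDS:
            d = demods[band]
            out.loc[e, band.lower() + "_amp"] = d.amp_ms[sel].mean()
        hf = demods["HF"]
        w = hf.amp_ms[sel]
        out.loc[e, "hf_freq"] = (np.average(hf.inst_freq_hz[sel], weights=w)
                                 if w.sum() > 0 else hf.f0)
        lf_amp, hf_amp = out.loc[e, "lf_amp"], out.loc[e, "hf_amp"]
        if hf_amp > 0:
            ratio = lf_amp / hf_amp
            out.loc[e, "lf_hf"] = ratio ** 2 if params.lfhf_convention == "power" else ratio
    return out


def hsi(series: Resampled2Hz, grid: EpochGrid, params: Params | None = None) -> np.ndarray:
    """HF spectral power concentration index per epoch, in percent.

    The 2 Hz series is cut into overlapping 512-point (256 s) windows at a
    30 s step. Each window is linearly detrended, Hann-windowed and
    Fourier-transformed (bin width 1/256 Hz); Hsi is 100 x the power within
    peak +/- W bins of the HF-band spectral peak, divided by the total
    HF-band power, assigned to the 30 s epoch at the window center.
    Windows touching invalid samples yield NaN.
    """
    params = params or Params()
    n_win = int(round(params.hsi_window_s * series.rate))          # 512
    step = int(round(grid.epoch_s * series.rate))                  # 60
    df = series.rate / n_win                                       # 1/256 Hz
    lo, hi = params.hf_band
    k_lo = int(np.ceil(lo / df))
    k_hi = int(np.floor(hi / df))
    W = params.hsi_halfwidth_bins
    window = np.hanning(n_win)

    out = np.full(grid.n_epochs, np.nan)
    times = series.times
    for s0 in range(0, len(series.rr_ms) - n_win + 1, step):
        seg_valid = series.valid[s0:s0 + n_win]
        center_t = times[s0] + 0.5 * params.hsi_window_s
        e = int(grid.index_of(center_t))
        if not (0 <= e < grid.n_epochs) or not seg_valid.all():
            continue
        seg = signal.detrend(series.rr_ms[s0:s0 + n_win], type="linear") * window
        power = np.abs(np.fft.rfft(seg)) ** 2
        band_power = power[k_lo:k_hi + 1]
        total = band_power.sum()
        if total <= 0:
            continue
        peak = k_lo + int(np.argmax(band_power))
        a, b = max(peak - W, k_lo), min(peak + W, k_hi)
        out[e] = 100.0 * power[a:b + 1].sum() / total
    return out


def compute_epoch_hrv(beats: BeatSeries, grid: EpochGrid,
                      params: Params | None = None) -> pd.DataFrame:
    """All HRV indices on the epoch grid: HR, SDRR, band amps, HF freq, LF/HF, Hsi."""
    params = params or Params()
    nn = extract_nn(beats)
    table = epoch_hr_sdrr(nn, grid, params)
    if len(nn) >= 4:
        res = resample_2hz(nn, start_time=grid.start_time,
                           duration_s=grid.n_epochs * grid.epoch_s, params=params)
        demods = {b: complex_demodulate(res, b, params) for b in BANDS}
        table = table.merge(epoch_band_stats(demods, res, grid, params), on="epoch_index")
        table["hsi"] = hsi(res, grid, params)
    else:
        for col in ("vlf_amp", "lf_amp", "hf_amp", "hf_freq", "lf_hf", "hsi"):
            table[col] = np.nan
    return table
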