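import numpy as np
import pytest

from posturehrv import (BeatSeries, Params, complex_demodulate,
                        epoch_band_stats, epoch_hr_sdrr, extract_nn, hsi,
                        resample_2hz)
from posturehrv.core import EpochGrid
from posturehrv.hrv import BANDS, NNSeries, Resampled2Hz


def beats_from_rr(rr_ms, labels=None, start=0.0):
    rr = np.asarray(rr_ms, dtype=float)
    times = start + np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    rr_col = np.concatenate([[np.nan], rr])
    lab = np.array(labels if labels is not None else ["N"] * len(times), dtype=object)
    return BeatSeries(times, rr_col, lab)


def tone_series(freq, amp, duration_s, mean=1000.0, rate=2.0):
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    x = mean + amp * np.sin(2 * np.pi * freq * t)
    return Resampled2Hz(0.0, rate, x, np.ones(n, dtype=bool))


# ---------------------------------------------------------------------------
# NN extraction

def test_all_sinus_keeps_every_interval():
    beats = beats_from_rr([1000.0] * 10)
    nn = extract_nn(beats)
    assert len(nn) == 10


def test_one_ectopic_drops_both_touching_intervals():
    labels = ["N"] * 11
    labels[5] = "V"
    nn = extract_nn(beats_from_rr([1000.0] * 10, labels))
    assert len(nn) == 8  # intervals ending at beats 5 and 6 dropped


def test_alternating_nv_leaves_no_nn_pairs():
    labels = ["N", "V"] * 5
    assert len(extract_nn(beats_from_rr([1000.0] * 9, labels))) == 0


# ---------------------------------------------------------------------------
# time-domain indices

def test_constant_rr_gives_hr60_sdrr0():
    beats = beats_from_rr([1000.0] * 40)
    grid = EpochGrid(0.0, 1)
    row = epoch_hr_sdrr(extract_nn(beats), grid).iloc[0]
    assert row.hr == pytest.approx(60.0)
    assert row.sdrr == pytest.approx(0.0)


def test_alternating_rr_closed_form_sample_sd():
    # 30 intervals of 800/1200 ms in one epoch: HR 60, SDRR 200*sqrt(30/29)
    # (start slightly early so the last interval's end stays inside the epoch)
    beats = beats_from_rr([800.0, 1200.0] * 15, start=-0.4)
    grid = EpochGrid(0.0, 1)
    row = epoch_hr_sdrr(extract_nn(beats), grid).iloc[0]
    assert row.hr == pytest.approx(60.0)
    assert row.sdrr == pytest.approx(200.0 * np.sqrt(30 / 29), rel=1e-12)


def test_too_few_nn_intervals_give_nan():
    beats = beats_from_rr([1000.0] * 5)
    row = epoch_hr_sdrr(extract_nn(beats), EpochGrid(0.0, 1)).iloc[0]
    assert np.isnan(row.hr) and np.isnan(row.sdrr)


def test_hr_sdrr_match_bruteforce_on_random_series():
    rng = np.random.default_rng(4)
    rr = rng.uniform(700, 1100, 300)
    beats = beats_from_rr(rr)
    nn = extract_nn(beats)
    grid = EpochGrid(0.0, int(nn.times[-1] // 30))
    table = epoch_hr_sdrr(nn, grid)
    for e in range(grid.n_epochs):
        sel = (nn.times >= 30 * e) & (nn.times < 30 * (e + 1))
        vals = nn.rr_ms[sel]
        if len(vals) >= 10:
            assert table.hr[e] == pytest.approx(60000.0 / vals.mean())
            assert table.sdrr[e] == pytest.approx(vals.std(ddof=1))
        else:
            assert np.isnan(table.hr[e])


# ---------------------------------------------------------------------------
# 2 Hz resampling

def test_resample_constant_is_exact():
    beats = beats_from_rr([1000.0] * 100)
    res = resample_2hz(extract_nn(beats))
    np.testing.assert_allclose(res.rr_ms[res.valid], 1000.0, atol=1e-9)
    assert np.all(np.diff(res.times) == pytest.approx(0.5))


def test_resample_tracks_slow_sine_within_2ms():
    # rr(t) = 1000 + 50 sin(2 pi 0.25 t) sampled at the beats themselves
    times = [0.0]
    while times[-1] < 120:
        rr = 1000.0 + 50.0 * np.sin(2 * np.pi * 0.25 * times[-1])
        times.append(times[-1] + rr / 1000.0)
    times = np.array(times)
    # spline the *analytic* rr value at each beat
    nn = NNSeries(times[1:], 1000.0 + 50.0 * np.sin(2 * np.pi * 0.25 * times[1:]))
    res = resample_2hz(nn)
    analytic = 1000.0 + 50.0 * np.sin(2 * np.pi * 0.25 * res.times)
    sel = res.valid
    assert np.abs(res.rr_ms[sel] - analytic[sel]).max() < 2.0


def test_long_gap_masked_invalid():
    rr = [1000.0] * 30
    beats = beats_from_rr(rr)
    nn = extract_nn(beats)
    nn.times[15:] += 10.0  # open a 10 s (11 s total) annotation gap
    res = resample_2hz(nn)
    in_gap = (res.times > nn.times[14]) & (res.times < nn.times[15])
    assert in_gap.any() and not res.valid[in_gap].any()
    assert res.valid[res.times < nn.times[14]].all()


def test_resample_needs_four_intervals():
    with pytest.raises(ValueError, match="4 NN"):
        resample_2hz(NNSeries(np.arange(3.0), np.full(3, 1000.0)))


# ---------------------------------------------------------------------------
# complex demodulation

def test_single_hf_tone_recovery():
    s = tone_series(0.25, 50.0, 1500.0)
    d = complex_demodulate(s, "HF")
    mid = slice(600, -600)
    assert abs(d.amp_ms[mid].mean() - 50.0) / 50.0 < 0.05
    assert abs(d.inst_freq_hz[mid].mean() - 0.25) < 0.005


def test_zero_signal_gives_zero_amp_and_center_freq():
    s = tone_series(0.25, 0.0, 600.0)
    d = complex_demodulate(s, "HF")
    np.testing.assert_allclose(d.amp_ms, 0.0, atol=1e-9)
    np.testing.assert_allclose(d.inst_freq_hz, d.f0)


def test_unknown_band_rejected():
    with pytest.raises(ValueError, match="band"):
        complex_demodulate(tone_series(0.25, 10, 600), "ULF")


def test_two_tone_crosstalk_below_5pct():
    n = int(1500 * 2)
    t = np.arange(n) / 2.0
    x = 1000 + 40.0 * np.sin(2 * np.pi * 0.10 * t) + 40.0 * np.sin(2 * np.pi * 0.25 * t)
    s = Resampled2Hz(0.0, 2.0, x, np.ones(n, bool))
    mid = slice(600, -600)
    lf = complex_demodulate(s, "LF")
    hf = complex_demodulate(s, "HF")
    assert abs(lf.amp_ms[mid].mean() - 40.0) / 40.0 < 0.05
    assert abs(hf.amp_ms[mid].mean() - 40.0) / 40.0 < 0.05
    assert abs(lf.inst_freq_hz[mid].mean() - 0.10) < 0.005
    assert abs(hf.inst_freq_hz[mid].mean() - 0.25) < 0.005


def test_band_amplitudes_invariant_to_rr_offset():
    s1 = tone_series(0.25, 40.0, 900.0, mean=900.0)
    s2 = tone_series(0.25, 40.0, 900.0, mean=1200.0)
    for band in BANDS:
        a1 = complex_demodulate(s1, band).amp_ms
        a2 = complex_demodulate(s2, band).amp_ms
        np.testing.assert_allclose(a1, a2, atol=1e-6)


# ---------------------------------------------------------------------------
# epoch band statistics

def _stationary_demods(lf_amp, hf_amp, duration=600.0):
    n = int(duration * 2)
    t = np.arange(n) / 2.0
    x = 1000 + lf_amp * np.sin(2 * np.pi * 0.10 * t) + hf_amp * np.sin(2 * np.pi * 0.25 * t)
    s = Resampled2Hz(0.0, 2.0, x, np.ones(n, bool))
    return {b: complex_demodulate(s, b) for b in BANDS}, s


@pytest.mark.parametrize("lf_amp,hf_amp,expected", [(30.0, 30.0, 1.0), (40.0, 20.0, 4.0)])
def test_lfhf_power_convention(lf_amp, hf_amp, expected):
    demods, s = _stationary_demods(lf_amp, hf_amp)
    grid = EpochGrid(0.0, 20)
    table = epoch_band_stats(demods, s, grid)
    interior = table.iloc[5:15]
    np.testing.assert_allclose(interior.lf_hf, expected, rtol=0.15)


def test_lfhf_amplitude_convention_flag():
    demods, s = _stationary_demods(40.0, 20.0)
    grid = EpochGrid(0.0, 20)
    table = epoch_band_stats(demods, s, grid, Params().replace(lfhf_convention="amplitude"))
    np.testing.assert_allclose(table.iloc[5:15].lf_hf, 2.0, rtol=0.08)


def test_invalid_epochs_are_nan():
    demods, s = _stationary_demods(30.0, 30.0)
    s.valid[130:150] = False  # inside epoch 2 (60-90 s)
    table = epoch_band_stats(demods, s, EpochGrid(0.0, 10))
    assert np.isnan(table.loc[2, "hf_amp"])
    assert not np.isnan(table.loc[5, "hf_amp"])


# ---------------------------------------------------------------------------
# Hsi

def test_hsi_pure_tone_above_95():
    rng = np.random.default_rng(5)
    n = int(1800 * 2)
    t = np.arange(n) / 2.0
    x = 1000 + 40.0 * np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 0.5, n)
    s = Resampled2Hz(0.0, 2.0, x, np.ones(n, bool))
    v = hsi(s, EpochGrid(0.0, 60))
    assert np.nanmean(v) >= 95.0


def test_hsi_white_noise_is_dilute():
    # flat HF spectrum: concentration ~ (2W+1)/64 plus peak-selection bias
    rng = np.random.default_rng(6)
    n = int(3600 * 2)
    x = 1000 + rng.normal(0, 30.0, n)
    s = Resampled2Hz(0.0, 2.0, x, np.ones(n, bool))
    v = hsi(s, EpochGrid(0.0, 120))
    assert 12.0 < np.nanmean(v) < 35.0


def test_hsi_bounded_0_100():
    rng = np.random.default_rng(7)
    n = int(1200 * 2)
    x = 1000 + rng.normal(0, 20, n) + 30 * np.sin(2 * np.pi * 0.3 * np.arange(n) / 2)
    s = Resampled2Hz(0.0, 2.0, x, np.ones(n, bool))
    v = hsi(s, EpochGrid(0.0, 40))
    finite = v[~np.isnan(v)]
    assert len(finite) and np.all((finite >= 0) & (finite <= 100))


def test_hsi_nan_when_window_invalid():
    n = int(900 * 2)
    x = np.full(n, 1000.0)
    valid = np.ones(n, bool)
    valid[500:520] = False
    s = Resampled2Hz(0.0, 2.0, x, valid)
    grid = EpochGrid(0.0, 30)
    v = hsi(s, grid)
    # windows covering the invalid span produce no value
    assert np.isnan(v[8])
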