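import numpy as np
import pytest

from posturehrv import (AccelSeries, gravity, label_epochs,
                        movement_flags, posture_percentages, sample_posture,
                        validate_classifier)
from posturehrv.posture import EPOCH_LABELS, body_axis_angles

FS = 31.25


def make_accel(xyz, fs=FS, start=0.0):
    xyz = np.asarray(xyz, dtype=float)
    return AccelSeries(start_time=start, fs=fs, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2])


# ---------------------------------------------------------------------------
# sample_posture

@pytest.mark.parametrize("vec,expected", [
    ((0, 0, 1), "supine"),          # sky along front axis: back-lying
    ((0, 1, 0), "left_lateral"),    # sky toward subject's right: on left side
    ((0, -1, 0), "right_lateral"),
    ((0, 0, -1), "prone"),
    ((1, 0, 0), "non_lying"),       # upright: head-foot axis vertical
    ((0, np.cos(np.radians(50)), np.sin(np.radians(50))), "left_lateral"),
])
def test_sample_posture_analytic_cases(vec, expected):
    assert sample_posture(np.array(vec, dtype=float)) == expected


def test_sample_posture_zero_vector_is_error():
    with pytest.raises(ValueError):
        sample_posture(np.zeros(3))


def test_sample_posture_matches_spherical_grid_oracle(posture_oracle, sphere_grid):
    """Vectorized classifier equals the literal rule at every off-boundary
    grid point, and the five regions partition the sphere."""
    got = sample_posture(sphere_grid)
    expected = np.array([posture_oracle(v) for v in sphere_grid], dtype=object)
    np.testing.assert_array_equal(got, expected)
    assert set(got) <= {"supine", "prone", "left_lateral", "right_lateral", "non_lying"}


def test_body_axis_angles_are_degrees():
    np.testing.assert_allclose(body_axis_angles(np.array([0.0, 0.0, 2.0])),
                               [90.0, 90.0, 0.0], atol=1e-9)


# ---------------------------------------------------------------------------
# movement detection

def test_zero_acceleration_has_no_movement():
    accel = make_accel(np.zeros((int(FS * 90), 3)))
    assert not movement_flags(accel).any()


def test_movement_band_oscillation_flags_its_epoch():
    n = int(FS * 90) + 1  # cover three full 30 s epochs (937.5 samples each)
    t = np.arange(n) / FS
    xyz = np.zeros((n, 3))
    xyz[:, 2] = 1.0
    in_second = (t >= 30) & (t < 60)
    xyz[in_second, 0] += 0.03 * np.sin(2 * np.pi * 2.5 * t[in_second])
    flags = movement_flags(make_accel(xyz))
    assert list(flags) == [False, True, False]


def test_slow_tilt_is_not_movement():
    # a full 1 g reorientation at 0.05 Hz is far outside the 2-3 Hz band
    n = int(FS * 120)
    t = np.arange(n) / FS
    xyz = np.column_stack([np.sin(2 * np.pi * 0.05 * t),
                           np.zeros(n), np.cos(2 * np.pi * 0.05 * t)])
    assert not movement_flags(make_accel(xyz)).any()


# ---------------------------------------------------------------------------
# gravity extraction

def test_gravity_passes_dc_unchanged():
    n = int(FS * 120)
    accel = make_accel(np.tile([0.0, 0.0, 1.0], (n, 1)))
    g = gravity(accel)
    interior = g[int(FS * 10):-int(FS * 10)]
    np.testing.assert_allclose(interior, np.tile([0, 0, 1.0], (len(interior), 1)), atol=1e-6)


def test_gravity_attenuates_1hz_ripple_by_20db():
    n = int(FS * 120)
    t = np.arange(n) / FS
    xyz = np.zeros((n, 3))
    xyz[:, 2] = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
    g = gravity(make_accel(xyz))
    ripple = g[int(FS * 10):-int(FS * 10), 2] - 1.0
    assert np.abs(ripple).max() < 0.5 / 10  # >= 20 dB down


def test_gravity_norm_near_1g_during_static_lying():
    rng = np.random.default_rng(3)
    n = int(FS * 120)
    xyz = np.tile([0.0, 1.0, 0.0], (n, 1)) + rng.normal(0, 0.005, (n, 3))
    g = gravity(make_accel(xyz))
    norms = np.linalg.norm(g[int(FS * 10):-int(FS * 10)], axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=0.01)


# ---------------------------------------------------------------------------
# epoch labeling

def _labels(fracs, per_epoch=int(FS * 30)):
    out = []
    for label, frac in fracs:
        out += [label] * int(round(frac * per_epoch))
    return np.array(out[:per_epoch], dtype=object)


def test_pure_epoch_keeps_its_posture():
    samples = _labels([("supine", 1.0)])
    assert label_epochs(samples, np.array([False]))[0] == "supine"


def test_majority_55_45_is_labeled_majority():
    samples = _labels([("supine", 0.55), ("left_lateral", 0.45)])
    assert label_epochs(samples, np.array([False]))[0] == "supine"


def test_exact_50_50_is_transition():
    per = int(FS * 30)  # 937 samples; use an even count for an exact tie
    samples = np.array(["supine"] * 468 + ["left_lateral"] * 468 + ["prone"], dtype=object)
    assert len(samples) == per
    # prone breaks the tie only if >50%; here no label exceeds half
    assert label_epochs(samples, np.array([False]))[0] == "transition"


def test_movement_flag_overrides_posture():
    samples = _labels([("supine", 1.0)])
    assert label_epochs(samples, np.array([True]))[0] == "movement"


def test_dominant_non_lying_epoch_is_non_lying():
    samples = _labels([("non_lying", 0.9), ("supine", 0.1)])
    assert label_epochs(samples, np.array([False]))[0] == "non_lying"


def test_label_epochs_invariant_to_sample_order_within_epoch():
    rng = np.random.default_rng(0)
    samples = _labels([("prone", 0.6), ("supine", 0.4)])
    shuffled = samples.copy()
    rng.shuffle(shuffled)
    a = label_epochs(samples, np.array([False]))
    b = label_epochs(shuffled, np.array([False]))
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# posture percentages

def test_percentages_equal_counts():
    labels = np.array(["supine", "right_lateral", "left_lateral", "prone"] * 3, dtype=object)
    pct = posture_percentages(labels)
    assert all(abs(v - 25.0) < 1e-12 for v in pct.values())


def test_percentages_exclude_transitions():
    labels = np.array(["supine"] * 3 + ["prone"] + ["transition"] * 4, dtype=object)
    pct = posture_percentages(labels)
    assert pct["supine"] == 75.0 and pct["prone"] == 25.0


def test_percentages_sum_to_100_and_order_invariant():
    rng = np.random.default_rng(1)
    labels = rng.choice(EPOCH_LABELS, size=200).astype(object)
    pct = posture_percentages(labels)
    assert abs(sum(pct.values()) - 100.0) < 1e-9
    shuffled = labels.copy()
    rng.shuffle(shuffled)
    assert posture_percentages(shuffled) == pct


def test_percentages_undefined_without_posture_epochs():
    labels = np.array(["transition", "movement"], dtype=object)
    assert all(np.isnan(v) for v in posture_percentages(labels).values())


# ---------------------------------------------------------------------------
# validation metrics

def test_perfect_prediction_scores_1():
    truth = np.array(["supine", "prone", "left_lateral", "right_lateral"] * 5, dtype=object)
    m = validate_classifier(truth, truth.copy())
    for posture in m:
        assert m[posture]["recall"] == 1.0 and m[posture]["precision"] == 1.0


def test_recall_09_when_one_of_ten_missed():
    truth = np.array(["right_lateral"] * 10, dtype=object)
    pred = np.array(["right_lateral"] * 9 + ["supine"], dtype=object)
    m = validate_classifier(truth, pred)
    assert m["right_lateral"]["recall"] == pytest.approx(0.9)
    assert m["right_lateral"]["precision"] == 1.0
    assert np.isnan(m["prone"]["recall"])  # no prone truth


def test_unknown_truth_label_is_error():
    with pytest.raises(ValueError, match="vocabulary"):
        validate_classifier(np.array(["sitting"], dtype=object),
                            np.array(["supine"], dtype=object))
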