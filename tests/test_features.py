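"""Feature battery: hand values, brute-force oracle equivalence, scale
behaviour, matrix assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from tremorkit import (
    FEATURE_NAMES,
    GroupLabel,
    TaskLabel,
    amplitude_features,
    approximate_entropy,
    build_matrix,
    feature_vector,
    variability_features,
)


# ---------------------------------------------------------------------------
# independent reference implementations (naive loops)
# ---------------------------------------------------------------------------


def naive_features(x):
    """All 12 features computed with explicit loops, independent of the
    package implementation."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    var_pop = sum((v - mean) ** 2 for v in x) / n
    sd_pop = math.sqrt(var_pop)
    if sd_pop > 0:
        z = [(v - mean) / sd_pop for v in x]
    else:
        z = [0.0] * n
    d1 = [x[i + 1] - x[i] for i in range(n - 1)]
    d2 = [x[i + 2] - 2 * x[i + 1] + x[i] for i in range(n - 2)]
    d1n = [z[i + 1] - z[i] for i in range(n - 1)]
    d2n = [z[i + 2] - 2 * z[i + 1] + z[i] for i in range(n - 2)]
    xs = sorted(x)

    def quantile(q):
        # linear interpolation, matching the conventional definition
        h = (n - 1) * q
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    var_samp = sum((v - mean) ** 2 for v in x) / (n - 1)
    return {
        "MAV": sum(abs(v) for v in x) / n,
        "RMS": math.sqrt(sum(v * v for v in x) / n),
        "PEAK": max(x),
        "MAVSDN": sum(abs(v) for v in d2n) / len(d2n),
        "MAVSD": sum(abs(v) for v in d2) / len(d2),
        "MAVFDN": sum(abs(v) for v in d1n) / len(d1n),
        "MAVFD": sum(abs(v) for v in d1) / len(d1),
        "INTERQ_RANGE": quantile(0.75) - quantile(0.25),
        "RANGE": max(x) - min(x),
        "STD": math.sqrt(var_samp),
        "VAR": var_samp,
        "APEN": naive_apen(x),
    }


def naive_apen(x, m=2, r_factor=0.2):
    """Pincus's ApEn as an explicit double loop (self-matches included,
    Chebyshev distance)."""
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def phi(mm):
        count = n - mm + 1
        templates = [x[i : i + mm] for i in range(count)]
        total = 0.0
        for a in templates:
            c = 0
            for b in templates:
                if max(abs(u - v) for u, v in zip(a, b)) <= r:
                    c += 1
            total += math.log(c / count)
        return total / count

    return phi(m) - phi(m + 1)


# ---------------------------------------------------------------------------
# hand-computable examples
# ---------------------------------------------------------------------------


def test_alternating_series_hand_values():
    x = np.array([1.0, -1.0, 1.0, -1.0])
    f = amplitude_features(x)
    assert f["MAV"] == 1 and f["RMS"] == 1 and f["PEAK"] == 1
    assert f["MAVFD"] == 2 and f["MAVSD"] == 4


def test_constant_series_degenerates_to_zero_differences():
    f = feature_vector(np.full(50, 3.0))
    assert f["MAV"] == 3.0
    for name in ("MAVFD", "MAVSD", "MAVFDN", "MAVSDN", "INTERQ_RANGE",
                 "RANGE", "STD", "VAR", "APEN"):
        assert f[name] == 0.0


def test_arange_variability_hand_values():
    f = variability_features(np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
    assert f["RANGE"] == 4.0
    assert f["VAR"] == 2.5
    assert f["STD"] == pytest.approx(math.sqrt(2.5))


def test_peak_is_signed_maximum():
    assert amplitude_features(np.array([-5.0, -2.0, -1.0]))["PEAK"] == -1.0


# ---------------------------------------------------------------------------
# oracle equivalence and invariants
# ---------------------------------------------------------------------------


def test_all_features_match_naive_oracle_on_random_vectors(rng):
    for _ in range(25):
        x = rng.standard_normal(rng.integers(30, 120))
        got = feature_vector(x)
        want = naive_features(x)
        for name in FEATURE_NAMES:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name


def test_apen_matches_naive_double_loop_on_white_noise(rng):
    x = rng.standard_normal(100)
    assert approximate_entropy(x) == pytest.approx(naive_apen(list(x)), abs=1e-10)


def test_apen_orders_sinusoid_below_shuffle(rng):
    t = np.arange(250) / 50.0
    sine = np.sin(2 * np.pi * 5 * t)
    ap_sine = approximate_entropy(sine)
    shuffled = sine.copy()
    rng.shuffle(shuffled)
    assert ap_sine < approximate_entropy(shuffled)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=hst.floats(min_value=0.1, max_value=100.0),
    seed=hst.integers(min_value=0, max_value=2**16),
)
def test_scale_behaviour_of_features(scale, seed):
    """Positive rescaling x -> c*x scales the amplitude statistics by c,
    the variance by c^2, and leaves the normalized-difference features
    and ApEn untouched (r is tied to the SD)."""
    x = np.random.default_rng(seed).standard_normal(80)
    base = feature_vector(x)
    scaled = feature_vector(scale * x)
    for name in ("MAV", "RMS", "STD", "RANGE", "INTERQ_RANGE", "MAVFD", "MAVSD"):
        assert scaled[name] == pytest.approx(scale * base[name], rel=1e-9)
    assert scaled["VAR"] == pytest.approx(scale**2 * base["VAR"], rel=1e-9)
    for name in ("MAVFDN", "MAVSDN", "APEN"):
        assert scaled[name] == pytest.approx(base[name], rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


def _toy_table(n_subjects=4, n_trials=5, rng=None):
    import pandas as pd

    rng = rng or np.random.default_rng(0)
    rows = []
    for s in range(n_subjects):
        for trial in range(1, n_trials + 1):
            for task in ("T1", "T2"):
                row = {
                    "subject_id": f"s{s}",
                    "group": "S_H" if s % 2 else "S_PD",
                    "trial": trial,
                    "task": task,
                }
                for method in ("FS", "IA", "IF"):
                    for ch in ("accel1", "gyro1", "mag1", "accel2", "gyro2",
                               "mag2", "emg1", "emg2"):
                        for f in FEATURE_NAMES:
                            row[f"{method}:{ch}:{f}"] = rng.standard_normal()
                rows.append(row)
    return pd.DataFrame(rows)


def test_column_count_tracks_combo_size():
    table = _toy_table()
    for combo, expect in ((("FS",), 96), (("FS", "IA"), 192),
                          (("FS", "IA", "IF"), 288)):
        fm = build_matrix(table, TaskLabel.T1, combo)
        assert fm.X.shape == (20, expect)


def test_full_cohort_matrix_dimensions():
    """38 subjects x 5 trials with a two-method combination gives the
    190 x 192 matrix the cohort layout implies."""
    table = _toy_table(n_subjects=38, n_trials=5)
    fm = build_matrix(table, TaskLabel.T2, ("FS", "IA"))
    assert fm.X.shape == (190, 192)


def test_row_order_of_input_is_irrelevant(rng):
    table = _toy_table()
    shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = build_matrix(table, TaskLabel.T1, ("FS",))
    b = build_matrix(shuffled, TaskLabel.T1, ("FS",))
    np.testing.assert_allclose(a.X, b.X)
    assert list(a.meta["subject_id"]) == list(b.meta["subject_id"])


def test_non_finite_feature_is_an_error_naming_the_cell():
    table = _toy_table()
    col = "FS:accel1:RMS"
    table.loc[3, col] = np.nan
    with pytest.raises(ValueError, match="FS:accel1:RMS"):
        build_matrix(table, TaskLabel(table.loc[3, "task"]), ("FS",))


def test_empty_combo_rejected():
    with pytest.raises(ValueError, match="nonempty"):
        build_matrix(_toy_table(), TaskLabel.T1, ())
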