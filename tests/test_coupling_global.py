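import numpy as np
import pytest

from acfc.bandpower import BandPowerSeries
from acfc.coupling import (CouplingMatrix, best_lag, build_network, classify_strength,
                           coupling_matrix, group_average, mean_link_strength)
from acfc.rates import RateSeries


def _bands(rng, n=500, n_bands=10, muscle="M1", step=1.0):
    return [
        BandPowerSeries(muscle, f"F{b + 1}", 1.0 + step * np.arange(n),
                        rng.standard_normal(n), step, 2.0, normalized=True)
        for b in range(n_bands)
    ]


def test_self_coupling_diagonal_is_one(rng):
    a = _bands(rng)
    mat = coupling_matrix(a, a)
    np.testing.assert_allclose(np.diag(mat.values), 1.0, atol=1e-12)
    assert mat.shape == (10, 10)


def test_matrix_entry_counts_muscle_and_rate(rng):
    a, b = _bands(rng, muscle="LegL"), _bands(rng, muscle="LegR")
    assert coupling_matrix(a, b).values.size == 100
    hr = RateSeries("hr", 1.0 + np.arange(500.0), 60 + rng.standard_normal(500), 1.0)
    mat = coupling_matrix(hr, b)
    assert mat.values.size == 10
    assert mat.row_labels == ["HR"] and mat.pair_id == ("Heart", "LegR")


def test_independent_white_noise_stays_below_null_bound(rng):
    a, b = _bands(rng, n=10000), _bands(rng, n=10000)
    mat = coupling_matrix(a, b)
    assert np.abs(mat.values).max() < 3 / np.sqrt(10000) * np.sqrt(3)
    assert np.abs(mat.values).mean() < 0.05


def test_every_entry_matches_two_pass_pearson(rng):
    a, b = _bands(rng, n=200), _bands(rng, n=200)
    mat = coupling_matrix(a, b)
    for i in range(10):
        for j in range(10):
            direct = np.corrcoef(a[i].values, b[j].values)[0, 1]
            assert abs(mat.values[i, j] - direct) < 1e-12


def test_zero_lag_symmetry_transpose(rng):
    a, b = _bands(rng, n=300), _bands(rng, n=300)
    ab = coupling_matrix(a, b).values
    ba = coupling_matrix(b, a).values
    np.testing.assert_allclose(ab, ba.T, atol=1e-12)


def test_scale_invariance_through_normalization(rng):
    from acfc.bandpower import zscore_global
    raw = [BandPowerSeries("M", f"F{b}", 1.0 + np.arange(300.0),
                           np.abs(rng.standard_normal(300)) + 0.1, 1.0, 2.0)
           for b in range(1, 11)]
    other = [zscore_global(s) for s in _scaled(raw, 1.0)]
    base = coupling_matrix([zscore_global(s) for s in raw], other).values
    scaled = coupling_matrix([zscore_global(s) for s in _scaled(raw, 7.3)], other).values
    np.testing.assert_allclose(base, scaled, atol=1e-12)


def _scaled(series_list, c):
    from dataclasses import replace
    return [replace(s, values=c * s.values, times=s.times.copy()) for s in series_list]


def test_zero_variance_series_names_the_band(rng):
    a = _bands(rng, n=100)
    b = _bands(rng, n=100)
    b[3].values[:] = 2.0
    with pytest.raises(ValueError, match="F4"):
        coupling_matrix(a, b)


def test_short_overlap_is_rejected(rng):
    a = _bands(rng, n=5)
    with pytest.raises(ValueError, match="overlap"):
        coupling_matrix(a, a)


# ---------------------------------------------------------------------------
# lag scan
# ---------------------------------------------------------------------------

def test_best_lag_recovers_constructed_shift(rng):
    n = 400
    vals = rng.standard_normal(n)
    a = BandPowerSeries("A", "F1", 1.0 + np.arange(n), vals, 1.0, 2.0)
    # b delayed by 2 steps: b(t) = a(t - 2)
    b = BandPowerSeries("B", "F1", 3.0 + np.arange(n), vals, 1.0, 2.0)
    lag, r = best_lag(a, b, [-3, -2, -1, 0, 1, 2, 3])
    assert lag == 2 and r > 0.999999


def test_best_lag_identity_and_null(rng):
    n = 2000
    a = BandPowerSeries("A", "F1", 1.0 + np.arange(n), rng.standard_normal(n), 1.0, 2.0)
    lag, r = best_lag(a, a, [-2, -1, 0, 1, 2])
    assert lag == 0 and abs(r - 1) < 1e-12
    b = BandPowerSeries("B", "F1", 1.0 + np.arange(n), rng.standard_normal(n), 1.0, 2.0)
    _, r_null = best_lag(a, b, [-2, -1, 0, 1, 2])
    assert r_null < 3 / np.sqrt(n)


# ---------------------------------------------------------------------------
# group averaging
# ---------------------------------------------------------------------------

def _mat(values, pair=("LegL", "LegR")):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    rows = [f"F{i+1}" for i in range(values.shape[0])]
    cols = [f"F{j+1}" for j in range(values.shape[1])]
    return CouplingMatrix(pair, rows, cols, values)


def test_group_average_is_elementwise_mean(rng):
    mats = [_mat(np.clip(rng.standard_normal((10, 10)) / 3, -1, 1)) for _ in range(7)]
    avg = group_average(mats)
    np.testing.assert_allclose(avg.values, np.mean([m.values for m in mats], axis=0),
                               atol=1e-12)
    assert avg.n_participants == 7
    assert (avg.cell_counts == 7).all()
    np.testing.assert_allclose(group_average([_mat([[0.2]]), _mat([[0.4]])]).values,
                               [[0.3]])
    single = group_average([mats[0]])
    np.testing.assert_array_equal(single.values, mats[0].values)


def test_group_average_ignores_missing_cells(rng):
    m1 = _mat(np.full((10, 10), 0.4))
    vals = np.full((10, 10), 0.2)
    vals[0, 0] = np.nan
    m2 = _mat(vals)
    avg = group_average([m1, m2])
    assert avg.values[0, 0] == 0.4 and avg.cell_counts[0, 0] == 1
    assert abs(avg.values[5, 5] - 0.3) < 1e-12


def test_group_average_shape_mismatch(rng):
    with pytest.raises(ValueError, match="mismatch"):
        group_average([_mat(np.zeros((10, 10))), _mat(np.zeros((1, 10)))])


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def test_strength_classes_follow_breakpoints():
    th = (0.20, 0.35, 0.50, 0.65)
    assert classify_strength(0.7, th) == "very strong"
    assert classify_strength(0.55, th) == "strong"
    assert classify_strength(0.4, th) == "intermediate"
    assert classify_strength(0.25, th) == "weak"
    assert classify_strength(0.1, th) == "below-threshold"
    # the same r lands in a different class under the results-style preset
    assert classify_strength(0.4, (0.05, 0.15, 0.25, 0.35)) == "very strong"


def test_six_pair_network_has_600_links(rng):
    muscles = ["LegL", "LegR", "BackL", "BackR"]
    mats = []
    for i, a in enumerate(muscles):
        for b in muscles[i + 1:]:
            mats.append(_mat(np.clip(rng.standard_normal((10, 10)) / 3, -1, 1), (a, b)))
    net = build_network(mats, thresholds="methods")
    assert net.n_links == 600
    assert len(net.nodes) == 40
    # class assignment consistent with the thresholds for every link
    for link in net.links:
        assert link.class_label == classify_strength(link.strength, net.class_thresholds)


def test_mean_link_strength(rng):
    m = _mat(np.full((10, 10), 0.25))
    assert abs(mean_link_strength(m) - 0.25) < 1e-12
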