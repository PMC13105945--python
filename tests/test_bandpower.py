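import numpy as np
import pytest
from scipy import signal as sp_signal

from acfc.bandpower import (band_power_series, detrend_series, make_band_scheme,
                            spectral_power, zscore_global)
from acfc.recording import ChannelKind, Recording

RATE = 1000.0


def _emg(samples, rate=RATE):
    return Recording("m1", ChannelKind.EMG, samples, rate)


# ---------------------------------------------------------------------------
# band scheme
# ---------------------------------------------------------------------------

def test_default_scheme_reproduces_printed_edges():
    scheme = make_band_scheme()
    edges = [(b.low, b.high) for b in scheme.bands]
    assert edges == [(10.0, 29.5), (30.0, 49.5), (65.0, 84.5), (85.0, 104.5),
                     (105.0, 124.5), (125.0, 144.5), (145.0, 164.5), (165.0, 184.5),
                     (185.0, 204.5), (205.0, 224.5)]
    assert scheme.bins_per_band == 39


def test_single_band_no_exclusions():
    scheme = make_band_scheme(low=20.0, width=10.0, count=1, exclusions=())
    assert [(b.low, b.high) for b in scheme.bands] == [(20.0, 30.0)]


def test_no_bin_assigned_twice_and_none_excluded():
    scheme = make_band_scheme()
    freqs = 10.0 + 0.5 * np.arange(480)
    member = scheme.bin_membership(freqs)
    counts = np.bincount(member[member >= 0], minlength=10)
    assert (counts == 39).all()
    for lo, hi in scheme.exclusions:
        in_zone = (freqs >= lo) & (freqs < hi)
        assert (member[in_zone] == -1).all()


def test_scheme_rejects_bands_beyond_nyquist():
    with pytest.raises(ValueError, match="Nyquist"):
        make_band_scheme(nyquist=200.0)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def test_two_second_window_gives_480_bins(rng):
    spec = spectral_power(rng.standard_normal(2000), RATE)
    assert spec.freqs.size == 480
    assert spec.freqs[0] == 10.0 and spec.freqs[-1] == 249.5
    assert (spec.power >= 0).all()


def test_zero_input_gives_zero_spectrum():
    spec = spectral_power(np.zeros(2000), RATE)
    assert np.allclose(spec.power, 0)


def test_sinusoid_peak_location_and_parseval_total():
    t = np.arange(2000) / RATE
    x = np.sin(2 * np.pi * 100.0 * t)
    spec = spectral_power(x, RATE)
    assert spec.freqs[int(np.argmax(spec.power))] == 100.0
    # taper-corrected Parseval oracle: total one-sided power of a unit
    # sinusoid under 'spectrum' scaling = (A^2/2) * N*sum(w^2)/(sum w)^2
    w = sp_signal.get_window("hamming", 2000)
    expected = 0.5 * 2000 * (w**2).sum() / w.sum() ** 2
    assert abs(spec.power.sum() - expected) / expected < 0.10


def test_window_too_short_for_bin_width_errors(rng):
    with pytest.raises(ValueError, match="too short"):
        spectral_power(rng.standard_normal(1000), RATE, bin_width=0.5)


# ---------------------------------------------------------------------------
# band power series
# ---------------------------------------------------------------------------

def test_window_count_and_step_bookkeeping(rng):
    rec = _emg(rng.standard_normal(60000))
    series = band_power_series(rec, make_band_scheme(), window=2.0, step=1.0)
    assert len(series) == 10
    for s in series:
        assert len(s) == 59            # floor((60-2)/1)+1
        assert s.step == 1.0
        np.testing.assert_allclose(np.diff(s.times), 1.0)
        assert s.times[0] == 1.0       # window center


def test_sinusoid_lands_in_band_f4():
    t = np.arange(60000) / RATE
    rec = _emg(np.sin(2 * np.pi * 100.0 * t))
    series = band_power_series(rec, make_band_scheme())
    total = {s.band_label: s.values.sum() for s in series}
    assert total["F4"] / sum(total.values()) > 0.95


def test_zero_signal_gives_all_zero_series():
    series = band_power_series(_emg(np.zeros(10000)), make_band_scheme())
    for s in series:
        assert np.allclose(s.values, 0)


def test_recording_shorter_than_window_errors(rng):
    with pytest.raises(ValueError, match="shorter than one"):
        band_power_series(_emg(rng.standard_normal(1500)), make_band_scheme(), window=2.0)


def test_band_power_requires_emg_kind(rng):
    rec = Recording("e", ChannelKind.EKG, rng.standard_normal(10000), RATE)
    with pytest.raises(ValueError, match="EMG"):
        band_power_series(rec, make_band_scheme())


def test_conservation_bands_equal_assigned_bins(rng):
    """Sum of P over all bands equals the sum of S over all assigned bins,
    window by window."""
    rec = _emg(rng.standard_normal(10000))
    scheme = make_band_scheme()
    series = band_power_series(rec, scheme, window=2.0, step=1.0)
    band_total = np.sum([s.values for s in series], axis=0)
    fmax = scheme.bands[-1].high
    for i in range(len(series[0])):
        window = rec.samples[i * 1000: i * 1000 + 2000]
        spec = spectral_power(window, RATE, fmin=scheme.bands[0].low, fmax=fmax)
        member = scheme.bin_membership(spec.freqs)
        np.testing.assert_allclose(band_total[i], spec.power[member >= 0].sum(),
                                   rtol=1e-10)


# ---------------------------------------------------------------------------
# normalization / detrending
# ---------------------------------------------------------------------------

def _series(values, step=1.0):
    from acfc.bandpower import BandPowerSeries
    values = np.asarray(values, dtype=float)
    return BandPowerSeries("m", "F1", 1.0 + step * np.arange(values.size), values,
                           step, 2.0)


def test_zscore_global_moments_and_idempotence():
    z = zscore_global(_series([1.0, 2.0, 3.0]))
    assert abs(z.values.mean()) < 1e-9 and abs(z.values.std() - 1) < 1e-9
    assert z.normalized
    z2 = zscore_global(z)
    np.testing.assert_allclose(z2.values, z.values, atol=1e-9)


def test_zscore_constant_series_is_degenerate():
    with pytest.raises(ValueError, match="constant"):
        zscore_global(_series(np.full(10, 3.0)))


def test_detrend_removes_ramp_keeps_oscillation(rng):
    n = 200
    t = np.arange(n, dtype=float)
    ramp = detrend_series(_series(2.0 + 0.5 * t))
    assert np.allclose(ramp.values, 0, atol=1e-9)
    wave = np.sin(2 * np.pi * t / 20)
    mixed = detrend_series(_series(wave + 0.3 * t))
    assert np.corrcoef(mixed.values, wave)[0, 1] > 0.99
    noise = rng.standard_normal(n)
    out = detrend_series(_series(noise))
    assert np.corrcoef(out.values, noise)[0, 1] > 0.99
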