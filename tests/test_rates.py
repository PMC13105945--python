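import numpy as np
import pytest

from acfc.rates import (PeakTrain, RateSeries, br_from_peaks, br_tfr, correct_artifacts,
                        detect_r_peaks, hr_series)
from acfc.recording import ChannelKind, Recording
from acfc.synth import SynthSpec, synth_ekg, synth_resp


# ---------------------------------------------------------------------------
# R-peak detection against generator ground truth
# ---------------------------------------------------------------------------

def test_constant_60bpm_all_beats_recovered():
    spec = SynthSpec(duration=180.0, hr_start=60.0, hr_end=60.0)
    rec, truth = synth_ekg(spec, seed=7)
    peaks = detect_r_peaks(rec)
    assert abs(len(peaks) - len(truth)) <= 1
    err = np.array([np.min(np.abs(truth.peak_times - t)) for t in peaks.peak_times])
    assert (err <= 0.010).mean() >= 0.99


def test_flat_signal_gives_empty_train():
    rec = Recording("e", ChannelKind.EKG, np.zeros(100000), 1000.0)
    assert len(detect_r_peaks(rec)) == 0


def test_ramp_gives_decreasing_rr():
    spec = SynthSpec(duration=120.0, hr_start=60.0, hr_end=120.0)
    rec, _ = synth_ekg(spec, seed=3)
    rr = np.diff(detect_r_peaks(rec).peak_times)
    # monotone decreasing up to a small detection jitter
    assert np.all(np.diff(rr) < 0.005)


def test_detector_rejects_non_ekg_and_low_rate(rng):
    with pytest.raises(ValueError, match="EKG"):
        detect_r_peaks(Recording("m", ChannelKind.EMG, rng.standard_normal(1000), 1000.0))
    with pytest.raises(ValueError, match="200"):
        detect_r_peaks(Recording("e", ChannelKind.EKG, rng.standard_normal(1000), 100.0))


# ---------------------------------------------------------------------------
# HR series
# ---------------------------------------------------------------------------

def test_constant_rr_maps_to_constant_bpm():
    for rr, bpm in [(1.0, 60.0), (0.5, 120.0)]:
        peaks = PeakTrain(rr * np.arange(1, 61))
        hr = hr_series(peaks)
        np.testing.assert_allclose(hr.values, bpm, atol=1e-6)
        assert hr.step == 1.0
        assert np.allclose(hr.times, np.round(hr.times))  # integer-second grid


def test_drifting_rr_matches_analytic_rate():
    rr = np.linspace(1.0, 0.6, 120)
    t = np.concatenate([[0.0], np.cumsum(rr)])
    hr = hr_series(PeakTrain(t))
    # analytic instantaneous rate at the later beat of each interval
    truth = np.interp(hr.times, t[1:], 60.0 / rr)
    assert np.abs(hr.values - truth).max() < 1.0


def test_hr_needs_three_peaks():
    with pytest.raises(ValueError, match="at least 3"):
        hr_series(PeakTrain(np.array([0.0, 1.0])))


def test_pipeline_recovers_programmed_hr_within_1_bpm():
    spec = SynthSpec(duration=180.0, hr_start=70.0, hr_end=100.0)
    rec, _ = synth_ekg(spec, seed=5)
    hr = correct_artifacts(hr_series(detect_r_peaks(rec)))
    truth = spec.hr(hr.times)
    assert np.abs(hr.values - truth).mean() < 1.0


# ---------------------------------------------------------------------------
# artifact correction
# ---------------------------------------------------------------------------

def _oracle_correct(values, times, window, k):
    out = values.copy()
    for i in range(len(values)):
        sel = np.abs(times - times[i]) <= window / 2 + 1e-9
        m, s = values[sel].mean(), values[sel].std()
        if s > 0 and abs(values[i] - m) > k * s:
            others = sel.copy()
            others[i] = False
            out[i] = values[others].mean()
    return out


def test_spike_replaced_by_local_baseline():
    values = np.full(60, 60.0)
    values[30] = 180.0
    series = RateSeries("hr", np.arange(60.0), values, 1.0)
    out = correct_artifacts(series, window=10.0, k=2.0)
    assert abs(out.values[30] - 60.0) < 1.0
    np.testing.assert_array_equal(np.delete(out.values, 30), np.delete(values, 30))


def test_constant_series_unchanged():
    series = RateSeries("hr", np.arange(30.0), np.full(30, 72.0), 1.0)
    np.testing.assert_array_equal(correct_artifacts(series).values, series.values)


def test_correction_matches_independent_oracle(rng):
    values = 70 + 3 * rng.standard_normal(200)
    values[[20, 90, 150]] += np.array([40.0, -35.0, 50.0])
    times = np.arange(200.0)
    series = RateSeries("hr", times, values, 1.0)
    out = correct_artifacts(series, window=10.0, k=2.0)
    np.testing.assert_allclose(out.values, _oracle_correct(values, times, 10.0, 2.0),
                               atol=1e-12)


def test_window_must_exceed_three_steps():
    series = RateSeries("hr", np.arange(30.0), np.full(30, 72.0), 1.0)
    with pytest.raises(ValueError, match="three steps"):
        correct_artifacts(series, window=2.0)


# ---------------------------------------------------------------------------
# breathing rate
# ---------------------------------------------------------------------------

def _resp_sine(freq_hz, duration=120.0, rate=1000.0):
    t = np.arange(int(duration * rate)) / rate
    return Recording("Resp", ChannelKind.RESP, np.sin(2 * np.pi * freq_hz * t), rate)


@pytest.mark.parametrize("freq,bpm", [(0.25, 15.0), (0.2, 12.0)])
def test_br_from_peaks_closed_form(freq, bpm):
    br = br_from_peaks(_resp_sine(freq))
    assert np.abs(br.values - bpm).max() < 0.5


def test_br_from_peaks_flat_signal_errors():
    rec = Recording("Resp", ChannelKind.RESP, np.zeros(60000), 1000.0)
    with pytest.raises(ValueError, match="no breaths"):
        br_from_peaks(rec)


def test_br_tfr_constant_rate():
    br = br_tfr(_resp_sine(0.25))
    assert br.step == 0.5
    np.testing.assert_allclose(np.diff(br.times), 0.5)
    interior = slice(4, -4)
    assert np.abs(br.values[interior] - 15.0).max() < 0.5


def test_br_tfr_chirp_tracks_truth():
    spec = SynthSpec(duration=300.0, br_start=12.0, br_end=24.0)
    rec = synth_resp(spec, seed=5)
    br = br_tfr(rec)
    truth = spec.br(br.times)
    assert np.abs(br.values - truth).max() < 1.5
    assert abs(br.values[0] - 12.0) < 1.5 and abs(br.values[-1] - 24.0) < 1.5
    # monotone increase apart from estimator jitter
    assert np.polyfit(br.times, br.values, 1)[0] > 0


def test_br_tfr_needs_full_window():
    with pytest.raises(ValueError, match="shorter"):
        br_tfr(_resp_sine(0.25, duration=10.0))
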