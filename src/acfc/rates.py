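"""Instantaneous heart-rate and breathing-rate time series.

Heart rate: R peaks are detected with the Pan-Tompkins cascade (band-pass
-> derivative -> squaring -> moving-window integration -> adaptive
thresholding), instantaneous HR = 60/RR is assigned at each beat and
cubic-spline resampled to a uniform 1-s grid aligned with the EMG
band-power timestamps.  Outliers beyond +-2 SD of the local 10-s window
mean are replaced by the local mean.

Breathing rate: either breath-peak detection (clean recordings) or a
windowed-spectrum ridge extractor (20-s windows, 0.5-s step, parabolic
peak interpolation, 2-s moving average) suited to exercise recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft, interpolate, signal

from .config import get_logger
from .recording import ChannelKind, Recording

__all__ = [
    "PeakTrain",
    "RateSeries",
    "detect_r_peaks",
    "hr_series",
    "correct_artifacts",
    "br_from_peaks",
    "br_tfr",
]

log = get_logger(__name__)

HR_BOUNDS = (25.0, 250.0)   # BPM clamps after spline resampling
BR_BOUNDS = (4.0, 80.0)     # breaths/min clamps
MIN_RR = 0.25               # physiological refractory floor, seconds


@dataclass
class PeakTrain:
    """Strictly increasing event times (R peaks or breath peaks), seconds."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size > 1 and not (np.diff(self.peak_times) > 0).all():
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.peak_times.size)


@dataclass
class RateSeries:
    """Uniformly sampled event-rate series in events/minute."""

    kind: str                # "hr" or "br"
    times: np.ndarray
    values: np.ndarray
    step: float

    def __post_init__(self) -> None:
        if self.kind not in ("hr", "br"):
            raise ValueError("kind must be 'hr' or 'br'")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# Pan-Tompkins R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(rec: Recording) -> PeakTrain:
    """Detect QRS complexes in an EKG channel (Pan-Tompkins cascade).

    Returns an empty train (with a logged warning) when no peaks are found.
    All filtering is zero-phase, so detected times are not systematically
    delayed relative to the underlying R waves.
    """
    if rec.kind != ChannelKind.EKG:
        raise ValueError(f"R-peak detection needs an EKG channel, got {rec.kind.value!r}")
    if rec.rate < 200:
        raise ValueError("R-peak detection needs a sampling rate of at least 200 Hz")
    fs = rec.rate
    x = rec.samples
    if np.ptp(x) == 0:
        log.warning("flat EKG signal: no R peaks found")
        return PeakTrain(peak_times=np.empty(0))

    # 1. band-pass around the QRS energy band
    sos = signal.butter(3, (5.0, 15.0), btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    # 2-3. derivative then squaring emphasise steep QRS slopes
    der = np.gradient(bp) * fs
    sq = der**2
    # 4. moving-window integration over 150 ms
    nmwi = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(nmwi) / nmwi, mode="same")

    # 5. candidate peaks with the physiological refractory spacing
    dist = max(1, int(round(MIN_RR * fs)))
    cand, _ = signal.find_peaks(mwi, distance=dist)
    if cand.size == 0:
        log.warning("no candidate QRS peaks found")
        return PeakTrain(peak_times=np.empty(0))

    # adaptive two-level thresholding (running signal/noise peak estimates)
    init = mwi[: int(min(len(mwi), 2 * fs))]
    spki = float(init.max()) * 0.5
    npki = float(init.mean()) * 0.5
    accepted: list[int] = []
    for idx in cand:
        peak = mwi[idx]
        thr = npki + 0.25 * (spki - npki)
        if peak > thr:
            spki = 0.125 * peak + 0.875 * spki
            accepted.append(int(idx))
        else:
            npki = 0.125 * peak + 0.875 * npki
    if not accepted:
        log.warning("adaptive threshold rejected all QRS candidates")
        return PeakTrain(peak_times=np.empty(0))

    # refine each detection to the local maximum of the raw waveform
    half = int(round(0.080 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(len(x), idx + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory floor, keeping the larger waveform peak
    keep: list[int] = []
    for idx in refined:
        if keep and (idx - keep[-1]) < dist:
            if x[idx] > x[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    return PeakTrain(peak_times=rec.start_time + np.asarray(keep) / fs)


# ---------------------------------------------------------------------------
# rate series from event trains
# ---------------------------------------------------------------------------

def _rate_from_peaks(
    peaks: PeakTrain, step: float, kind: str, bounds: tuple[float, float]
) -> RateSeries:
    if len(peaks) < 3:
        raise ValueError(f"need at least 3 events to build a {kind} series, got {len(peaks)}")
    t = peaks.peak_times
    intervals = np.diff(t)
    rate_vals = 60.0 / intervals
    # causal convention: each interval's rate is assigned at the later event
    anchor = t[1:]
    spline = interpolate.CubicSpline(anchor, rate_vals)
    t0 = np.ceil(anchor[0] / step - 1e-9) * step
    t1 = np.floor(anchor[-1] / step + 1e-9) * step
    grid = t0 + step * np.arange(int(round((t1 - t0) / step)) + 1)
    vals = np.clip(spline(grid), *bounds)
    return RateSeries(kind=kind, times=grid, values=vals, step=step)


def hr_series(peaks: PeakTrain, step: float = 1.0) -> RateSeries:
    """Instantaneous heart rate (60/RR, BPM) spline-resampled to ``step`` s.

    Grid timestamps are multiples of ``step`` so they coincide with the EMG
    band-power window centers at the same resolution.
    """
    return _rate_from_peaks(peaks, step, "hr", HR_BOUNDS)


def correct_artifacts(rate: RateSeries, window: float = 10.0, k: float = 2.0) -> RateSeries:
    """Replace rate samples departing more than ``k`` SD from their local mean.

    The window is centered on the evaluated point and includes it when the
    mean/SD used for *flagging* are computed; a flagged point is replaced by
    the mean of the *other* samples in its window, so an isolated spike is
    restored to the local baseline.
    """
    if not window > 3 * rate.step:
        raise ValueError("artifact window must exceed three steps")
    v = rate.values
    n = len(v)
    half = window / 2
    out = v.copy()
    for i in range(n):
        sel = np.abs(rate.times - rate.times[i]) <= half + 1e-9
        m = v[sel].mean()
        s = v[sel].std()
        if s > 0 and abs(v[i] - m) > k * s:
            others = sel.copy()
            others[i] = False
            if others.any():
                out[i] = v[others].mean()
    return replace(rate, values=out, times=rate.times.copy())


def br_from_peaks(rec: Recording, step: float = 0.5) -> RateSeries:
    """Breathing rate from breath-peak detection (clean, artifact-free signals)."""
    if rec.kind != ChannelKind.RESP:
        raise ValueError(f"breathing-rate extraction needs a resp channel, got {rec.kind.value!r}")
    x = rec.samples
    if np.ptp(x) == 0:
        raise ValueError("flat respiratory signal: no breaths found")
    dist = max(1, int(round(60.0 / BR_BOUNDS[1] * rec.rate)))
    peaks, _ = signal.find_peaks(x, prominence=0.5 * np.std(x), distance=dist)
    if peaks.size < 3:
        raise ValueError(f"only {peaks.size} breaths found; need at least 3")
    train = PeakTrain(peak_times=rec.start_time + peaks / rec.rate)
    return _rate_from_peaks(train, step, "br", BR_BOUNDS)


# ---------------------------------------------------------------------------
# TFR breathing rate (windowed-spectrum ridge)
# ---------------------------------------------------------------------------

def br_tfr(
    rec: Recording,
    window: float = 20.0,
    step: float = 0.5,
    smooth: float = 2.0,
    fmin: float = 0.05,
    fmax: float = 1.0,
) -> RateSeries:
    """Breathing rate from the dominant spectral ridge of the belt signal.

    Each ``window``-long segment (>= 4 respiratory cycles at rest) is
    linearly detrended, Hamming-tapered and zero-padded; the highest power
    bin inside [fmin, fmax] Hz is refined by parabolic interpolation and
    converted to breaths/min.  The series (one value per ``step``) is then
    smoothed with a ``smooth``-second moving average.  Windows with no
    in-band peak are bridged by linear interpolation.
    """
    if rec.kind != ChannelKind.RESP:
        raise ValueError(f"breathing-rate extraction needs a resp channel, got {rec.kind.value!r}")
    if rec.duration < window:
        raise ValueError("recording shorter than one analysis window")
    fs = rec.rate
    nwin = int(round(window * fs))
    hop = int(round(step * fs))
    views = sliding_window_view(rec.samples, nwin)[::hop]
    n_windows = views.shape[0]

    nfft = int(fft.next_fast_len(4 * nwin))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    band = np.flatnonzero((freqs >= fmin) & (freqs <= fmax))
    taper = signal.get_window("hamming", nwin)

    ridge = np.full(n_windows, np.nan)
    chunk = max(1, int(2e7 // nfft))
    tgrid = np.arange(nwin)
    for c0 in range(0, n_windows, chunk):
        block = views[c0 : c0 + chunk].astype(float)
        block = signal.detrend(block, axis=1, type="linear")
        spec = np.fft.rfft(block * taper, n=nfft, axis=1)
        pxx = spec.real**2 + spec.imag**2
        sub = pxx[:, band]
        imax = np.argmax(sub, axis=1)
        for j in range(block.shape[0]):
            i = imax[j]
            if sub[j, i] <= 0 or i == 0 or i == len(band) - 1:
                continue  # no usable in-band peak -> gap, bridged below
            pm, p0, pp = sub[j, i - 1], sub[j, i], sub[j, i + 1]
            denom = pm - 2 * p0 + pp
            delta = 0.0 if denom == 0 else 0.5 * (pm - pp) / denom
            ridge[c0 + j] = (freqs[band[i]] + delta * (freqs[1] - freqs[0])) * 60.0

    times = rec.start_time + window / 2 + step * np.arange(n_windows)
    valid = np.isfinite(ridge)
    if not valid.any():
        raise ValueError("no spectral peak found inside the respiratory band in any window")
    if not valid.all():
        log.warning("breathing-rate ridge missing in %d/%d windows; gaps interpolated",
                    int((~valid).sum()), n_windows)
        ridge = np.interp(times, times[valid], ridge[valid])

    ksize = max(1, int(round(smooth / step)))
    kernel = np.ones(ksize)
    smoothed = np.convolve(ridge, kernel, mode="same") / np.convolve(
        np.ones_like(ridge), kernel, mode="same"
    )
    return RateSeries(kind="br", times=times, values=np.clip(smoothed, *BR_BOUNDS), step=step)
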