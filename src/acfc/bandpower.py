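"""Windowed spectral decomposition of EMG into per-band power time series.

The EMG signal is cut into short windows (2 s with a 1-s step by default;
20 s / 0.5 s for respiratory-muscular analyses).  Each window is tapered
and Fourier-transformed as a single segment — equivalent to a short-time
Fourier transform — yielding spectral power S(f, t_i) on a 0.5-Hz bin grid
over [10, 250) Hz (480 bins for a 2-s window).  Power is then summed over
ten 19.5-Hz-wide frequency bands F1..F10 (39 half-Hz bins each, half-open
[low, low+width) convention) that skip the 50-65 Hz interval affected by
the mains notch:

    P(F_m, t_i) = sum over f_j in F_m of S(f_j, t_i)

Finally each band series is normalised to zero mean and unit SD so the
coupling analysis compares relative fluctuations, not absolute amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .config import get_logger
from .recording import ChannelKind, Recording

__all__ = [
    "Band",
    "BandScheme",
    "Spectrum",
    "BandPowerSeries",
    "make_band_scheme",
    "spectral_power",
    "band_power_series",
    "zscore_global",
    "detrend_series",
]

log = get_logger(__name__)


# ---------------------------------------------------------------------------
# band scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One frequency band [low, high] with printed-edge labels in Hz.

    Bin membership is half-open: grid frequencies f with low <= f < high.
    """

    label: str
    low: float
    high: float


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping, equal-width frequency bands on a bin grid."""

    bands: tuple[Band, ...]
    bin_width: float
    exclusions: tuple[tuple[float, float], ...] = ()

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    @property
    def bins_per_band(self) -> int:
        b = self.bands[0]
        return int(round((b.high - b.low) / self.bin_width))

    def band_bins(self, band: Band) -> np.ndarray:
        """Grid frequencies belonging to ``band`` (half-open convention)."""
        n = int(round((band.high - band.low) / self.bin_width))
        return band.low + self.bin_width * np.arange(n)

    def bin_membership(self, freqs: np.ndarray) -> np.ndarray:
        """Map each grid frequency to a band index (-1 = unassigned)."""
        out = np.full(freqs.shape, -1, dtype=int)
        half = self.bin_width / 2
        for i, band in enumerate(self.bands):
            mask = (freqs >= band.low - half / 10) & (freqs < band.high - half / 10)
            out[mask] = i
        return out


def make_band_scheme(
    low: float = 10.0,
    width: float = 19.5,
    count: int = 10,
    bin_width: float = 0.5,
    exclusions: tuple[tuple[float, float], ...] = ((50.0, 65.0),),
    nyquist: float | None = None,
) -> BandScheme:
    """Build ``count`` equal-width bands starting at ``low``, skipping exclusions.

    Consecutive bands are separated by one bin (printed edges [10-29.5],
    [30-49.5], ...), and any band that would overlap an exclusion zone is
    pushed past it — reproducing the default scheme F1=[10-29.5] ...
    F10=[205-224.5] with the 50-65 Hz mains interval excluded.
    """
    if width <= 0 or bin_width <= 0 or count < 1:
        raise ValueError("width, bin_width and count must be positive")
    ratio = width / bin_width
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("band width must be a multiple of bin_width")
    for lo, hi in exclusions:
        if abs(lo / bin_width - round(lo / bin_width)) > 1e-9 or \
           abs(hi / bin_width - round(hi / bin_width)) > 1e-9:
            raise ValueError("exclusion zones must be aligned to the bin grid")

    bands: list[Band] = []
    start = low
    for m in range(1, count + 1):
        # skip forward past any exclusion zone the band would touch
        moved = True
        while moved:
            moved = False
            for lo, hi in exclusions:
                if start < hi and start + width > lo:
                    start = hi
                    moved = True
        bands.append(Band(label=f"F{m}", low=round(start, 9), high=round(start + width, 9)))
        start = start + width + bin_width
    if nyquist is not None and bands[-1].high >= nyquist:
        raise ValueError(
            f"band scheme reaches {bands[-1].high} Hz, at or beyond Nyquist {nyquist} Hz"
        )
    return BandScheme(bands=tuple(bands), bin_width=bin_width,
                      exclusions=tuple(tuple(z) for z in exclusions))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """Single-window power spectrum on a uniform bin grid."""

    freqs: np.ndarray
    power: np.ndarray
    window_center: float = float("nan")


def _power_matrix(
    windows: np.ndarray,
    rate: float,
    bin_width: float,
    fmin: float,
    fmax: float,
    taper: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window power on the output bin grid.

    ``windows`` has shape (n_windows, n_samples).  Each window is treated
    as a single tapered segment; native FFT bins are summed onto the
    coarser output grid when the window is longer than 1/bin_width.
    Returns (freqs, power) with power of shape (n_windows, n_bins).
    """
    n = windows.shape[1]
    native_df = rate / n
    if native_df > bin_width * (1 + 1e-9):
        raise ValueError(
            f"window of {n / rate:g} s is too short for {bin_width:g} Hz bins "
            f"(needs at least {1 / bin_width:g} s)"
        )
    win = signal.get_window(taper, n)
    detr = windows - windows.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(detr * win, axis=1)
    # 'spectrum' scaling: power per bin, one-sided
    scale = 2.0 / win.sum() ** 2
    pxx = (spec.real**2 + spec.imag**2) * scale
    pxx[:, 0] /= 2.0
    if n % 2 == 0:
        pxx[:, -1] /= 2.0
    native_freqs = np.fft.rfftfreq(n, 1.0 / rate)

    n_bins = int(round((fmax - fmin) / bin_width))
    freqs = fmin + bin_width * np.arange(n_bins)
    k = np.floor((native_freqs - fmin + bin_width / 2) / bin_width + 1e-9).astype(int)
    keep = (k >= 0) & (k < n_bins)
    power = np.zeros((windows.shape[0], n_bins))
    np.add.at(power.T, k[keep], pxx[:, keep].T)
    return freqs, power


def spectral_power(
    window_samples: np.ndarray,
    rate: float,
    bin_width: float = 0.5,
    fmin: float = 10.0,
    fmax: float = 250.0,
    taper: str = "hamming",
) -> Spectrum:
    """Power spectrum of one analysis window on the [fmin, fmax) bin grid.

    A 2-s window with 0.5-Hz bins over [10, 250) Hz yields 480 power values.
    """
    x = np.atleast_2d(np.asarray(window_samples, dtype=float))
    if rate < 2 * fmax:
        raise ValueError(f"rate {rate} cannot resolve fmax={fmax} (needs rate >= {2 * fmax})")
    freqs, power = _power_matrix(x, rate, bin_width, fmin, fmax, taper)
    return Spectrum(freqs=freqs, power=power[0])


# ---------------------------------------------------------------------------
# band power time series
# ---------------------------------------------------------------------------

@dataclass
class BandPowerSeries:
    """Spectral power of one EMG band sampled at window centers.

    ``times`` are the centers of the analysis windows (seconds, uniform
    ``step``); ``values`` the summed in-band power (raw, or z-scored when
    ``normalized`` is set).
    """

    muscle_id: str
    band_label: str
    times: np.ndarray
    values: np.ndarray
    step: float
    window_length: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, self.step, atol=1e-6):
                raise ValueError("times must be uniform at the stated step")

    def __len__(self) -> int:
        return int(self.values.size)


def band_power_series(
    rec: Recording,
    scheme: BandScheme,
    window: float = 2.0,
    step: float = 1.0,
    taper: str = "hamming",
    fmin: float | None = None,
    fmax: float | None = None,
) -> list[BandPowerSeries]:
    """Band-power time series P(F_m, t_i), one series per band of ``scheme``.

    Only windows fully contained in the recording are emitted; the series
    step equals ``step`` exactly and timestamps sit at window centers
    (start + window/2 + i*step).
    """
    if rec.kind != ChannelKind.EMG:
        raise ValueError(f"band power is defined for EMG channels, got kind={rec.kind.value!r}")
    nwin = int(round(window * rec.rate))
    hop = int(round(step * rec.rate))
    if hop < 1 or nwin < 2:
        raise ValueError("window and step must be positive")
    if rec.n_samples < nwin:
        raise ValueError(
            f"recording of {rec.duration:g} s is shorter than one {window:g} s window"
        )
    if nwin < 500:
        log.warning("analysis window holds only %d samples (<500); high bands may be "
                    "poorly resolved", nwin)
    if fmin is None:
        fmin = scheme.bands[0].low
    if fmax is None:
        # grid must extend past the last band's half-open upper edge
        fmax = scheme.bands[-1].high
    if fmax > rec.rate / 2:
        raise ValueError(f"band scheme needs frequencies up to {fmax} Hz, beyond "
                         f"Nyquist {rec.rate / 2} Hz")

    views = sliding_window_view(rec.samples, nwin)[::hop]
    freqs, power = _power_matrix(views, rec.rate, scheme.bin_width, fmin, fmax, taper)
    membership = scheme.bin_membership(freqs)

    n_windows = views.shape[0]
    centers = rec.start_time + window / 2 + step * np.arange(n_windows)
    out: list[BandPowerSeries] = []
    for i, band in enumerate(scheme.bands):
        vals = power[:, membership == i].sum(axis=1)
        out.append(BandPowerSeries(
            muscle_id=rec.channel_id, band_label=band.label,
            times=centers.copy(), values=vals, step=step, window_length=window,
        ))
    return out


def zscore_global(series: BandPowerSeries) -> BandPowerSeries:
    """Normalise a series to zero mean and unit SD over its full length."""
    sd = float(np.std(series.values))
    if sd == 0:
        raise ValueError(
            f"{series.muscle_id}/{series.band_label}: constant series (dead channel?) "
            "cannot be z-scored"
        )
    vals = (series.values - series.values.mean()) / sd
    return replace(series, values=vals, times=series.times.copy(), normalized=True)


def detrend_series(series: BandPowerSeries) -> BandPowerSeries:
    """Remove the least-squares linear trend (control analysis for protocols
    with slow monotonic power drift)."""
    if len(series) < 3:
        raise ValueError("detrending needs at least 3 points")
    vals = signal.detrend(series.values, type="linear")
    return replace(series, values=vals, times=series.times.copy())
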