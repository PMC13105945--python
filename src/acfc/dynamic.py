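"""Windowed coupling time series and their distribution profiles.

The band-power (or rate) series are cut into short windows (6 s with a
3-s step by default, covering one full squat cycle) and *locally*
normalised: within each window both sub-series are z-scored to zero mean
and unit SD, which preserves the local fluctuation pattern while removing
slow amplitude drifts.  The per-window coupling value is then

    C(t_i) = 1/(W-1) * sum_j  P1_hat(t_i, j) * P2_hat(t_i, j)

which equals the Pearson coefficient computed on that window.  The
resulting coupling time series (100 per muscle pair, 600 for the
four-muscle network; 10 per rate-muscle pair) are summarised as
peak-rescaled histograms with bin width dc = 0.05 on [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bandpower import BandPowerSeries
from .config import get_logger
from .rates import RateSeries

__all__ = [
    "CouplingTimeSeries",
    "HistogramProfile",
    "windowed_coupling",
    "windowed_coupling_all",
    "histogram_profile",
]

log = get_logger(__name__)


@dataclass
class CouplingTimeSeries:
    """Per-window coupling values for one link at fixed step.

    Missing values (windows where one sub-series had zero variance) are
    stored as NaN, never imputed.
    """

    pair_id: tuple[str, str]
    link_id: tuple[str, str]
    times: np.ndarray
    values: np.ndarray
    window_length: float
    step: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ValueError("coupling values must lie in [-1, 1]")

    def __len__(self) -> int:
        return int(self.values.size)

    def valid_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def _label(series) -> str:
    if isinstance(series, RateSeries):
        return series.kind.upper()
    return series.band_label


def _system(series) -> str:
    if isinstance(series, RateSeries):
        return "Heart" if series.kind == "hr" else "Respiration"
    return series.muscle_id


def _window_starts(n: int, w: int, hop: int) -> int:
    return (n - w) // hop + 1 if n >= w else 0


def windowed_coupling(
    a,
    b,
    window: float = 6.0,
    step: float = 3.0,
    lag: float = 0.0,
) -> CouplingTimeSeries:
    """Locally normalised coupling between two series in sliding windows.

    Both inputs must share their sampling step and time support; ``lag``
    shifts ``b`` (in seconds, a multiple of the series step) before
    windowing.  Windows must contain at least 4 samples; windows where
    either sub-series is constant yield NaN (flagged missing, logged).
    """
    if abs(a.step - b.step) > 1e-9:
        raise ValueError("both series must share the same step")
    dt = a.step
    lag_steps = int(round(lag / dt))
    if abs(lag_steps * dt - lag) > 1e-9:
        raise ValueError(f"lag {lag} s is not a multiple of the series step {dt} s")

    ia = np.round(a.times / dt).astype(int)
    ib = np.round(b.times / dt).astype(int)
    common = np.intersect1d(ia, ib - lag_steps)
    if common.size == 0 or np.any(np.diff(common) != 1):
        # keep only the longest contiguous run of shared support
        if common.size == 0:
            raise ValueError("series have no overlapping time support")
        breaks = np.flatnonzero(np.diff(common) != 1)
        segs = np.split(common, breaks + 1)
        common = max(segs, key=len)
    av = a.values[np.searchsorted(ia, common)]
    bv = b.values[np.searchsorted(ib, common + lag_steps)]

    w = int(round(window / dt))
    hop = int(round(step / dt))
    if w < 4:
        raise ValueError(f"window of {window:g} s holds only {w} samples; need at least 4")
    n_windows = _window_starts(common.size, w, hop)
    if n_windows < 1:
        raise ValueError("series shorter than one coupling window")

    wa = sliding_window_view(av, w)[::hop].astype(float)
    wb = sliding_window_view(bv, w)[::hop].astype(float)
    sa = wa.std(axis=1, ddof=1)
    sb = wb.std(axis=1, ddof=1)
    bad = (sa == 0) | (sb == 0)
    sa[sa == 0] = 1.0
    sb[sb == 0] = 1.0
    za = (wa - wa.mean(axis=1, keepdims=True)) / sa[:, None]
    zb = (wb - wb.mean(axis=1, keepdims=True)) / sb[:, None]
    vals = (za * zb).sum(axis=1) / (w - 1)
    vals = np.clip(vals, -1.0, 1.0)
    if bad.any():
        log.warning("%d/%d coupling windows had a zero-variance sub-series; flagged missing",
                    int(bad.sum()), n_windows)
        vals[bad] = np.nan

    # window center time: mean of the first/last sample times in the window
    t0 = common[0] * dt
    centers = t0 + (w - 1) * dt / 2 + step * np.arange(n_windows)
    return CouplingTimeSeries(
        pair_id=(_system(a), _system(b)), link_id=(_label(a), _label(b)),
        times=centers, values=vals, window_length=window, step=step,
    )


def windowed_coupling_all(
    a_list,
    b_list,
    window: float = 6.0,
    step: float = 3.0,
    lag: float = 0.0,
) -> list[CouplingTimeSeries]:
    """All pairwise coupling time series between two sets of series
    (10 x 10 band sets give 100 link series per system pair)."""
    if isinstance(a_list, (BandPowerSeries, RateSeries)):
        a_list = [a_list]
    if isinstance(b_list, (BandPowerSeries, RateSeries)):
        b_list = [b_list]
    return [
        windowed_coupling(a, b, window=window, step=step, lag=lag)
        for a in a_list
        for b in b_list
    ]


@dataclass
class HistogramProfile:
    """Histogram of coupling values over [-1, 1] at bin width dc,
    rescaled so the modal bin equals 1."""

    bin_edges: np.ndarray
    counts: np.ndarray
    rescaled: np.ndarray

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


def histogram_profile(cts: CouplingTimeSeries, dc: float = 0.05) -> HistogramProfile:
    """Distribution profile of a coupling time series (missing values excluded)."""
    if not (0 < dc <= 2):
        raise ValueError("bin width dc must lie in (0, 2]")
    vals = cts.valid_values()
    if vals.size == 0:
        raise ValueError("coupling series has no non-missing values")
    n_bins = int(round(2.0 / dc))
    edges = -1.0 + dc * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    rescaled = counts / counts.max()
    return HistogramProfile(bin_edges=edges, counts=counts, rescaled=rescaled)
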