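"""Quantifying the temporal variability of coupling time series.

Three complementary views of a coupling series C(t_i):

* static moments — SD (fluctuation magnitude), kurtosis (spikiness; Pearson
  convention, normal = 3, with excess alongside) and skewness (asymmetry);
* detrended fluctuation analysis (DFA) — the RMS fluctuation F(n) of the
  mean-centred integrated series after per-window polynomial detrending,
  whose power-law slope alpha captures fractal temporal structure
  (alpha = 0.5 uncorrelated, 1.5 random walk, 0.5 < alpha < 1.5 persistent);
* magnitude-sign decomposition of the increments dC(t_i) = C(t_{i+1}) - C(t_i),
  separating nonlinear (|dC|) from linear (sgn dC) characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import get_logger
from .dynamic import CouplingTimeSeries

__all__ = [
    "VariabilityStats",
    "DFAResult",
    "MagnitudeSignSeries",
    "static_stats",
    "dfa",
    "magnitude_sign",
    "default_dfa_scales",
]

log = get_logger(__name__)


# ---------------------------------------------------------------------------
# static moments
# ---------------------------------------------------------------------------

@dataclass
class VariabilityStats:
    """Moment summary of one coupling time series.

    ``kurtosis`` uses the Pearson convention (normal distribution = 3);
    ``excess_kurtosis`` = kurtosis - 3.  ``skewness`` is the biased sample
    coefficient g1.  Higher moments of a constant series are NaN.
    """

    pair_id: tuple[str, str]
    link_id: tuple[str, str]
    sd: float
    kurtosis: float
    excess_kurtosis: float
    skewness: float
    n: int
    conventions: str = "sd: ddof=1; kurtosis: Pearson (normal=3), biased; skewness: g1, biased"


def static_stats(cts: CouplingTimeSeries, min_n: int = 8) -> VariabilityStats:
    """SD, kurtosis and skewness of the non-missing coupling values."""
    vals = cts.valid_values()
    if vals.size < min_n:
        raise ValueError(f"need at least {min_n} non-missing values, got {vals.size}")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        kurt, skew = float("nan"), float("nan")
        log.warning("constant coupling series %s/%s: higher moments undefined",
                    cts.pair_id, cts.link_id)
    else:
        kurt = float(stats.kurtosis(vals, fisher=False, bias=True))
        skew = float(stats.skew(vals, bias=True))
    return VariabilityStats(
        pair_id=cts.pair_id, link_id=cts.link_id, sd=sd,
        kurtosis=kurt, excess_kurtosis=kurt - 3.0, skewness=skew, n=int(vals.size),
    )


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

@dataclass
class DFAResult:
    scales: np.ndarray          # window sizes n (samples)
    fluctuation: np.ndarray     # F(n) per scale
    alpha: float                # log-log slope over fit_range
    fit_range: tuple[int, int]
    detrend_order: int


def default_dfa_scales(n: int, n_scales: int = 15, smallest: int = 4) -> np.ndarray:
    """~``n_scales`` log-spaced integer scales from ``smallest`` to n/4."""
    largest = n // 4
    if largest < smallest:
        raise ValueError(f"series of length {n} too short for DFA (needs >= {4 * smallest})")
    grid = np.geomspace(smallest, largest, n_scales)
    return np.unique(np.round(grid).astype(int))


def dfa(
    series,
    scales=None,
    detrend_order: int = 1,
    fit_range: tuple[int, int] | None = None,
) -> DFAResult:
    """Detrended fluctuation analysis of a real sequence.

    The profile Y(k) is the cumulative sum of the mean-centred series.  For
    each scale n the profile is split into non-overlapping windows (both
    from the start and from the end of the series, so no samples are
    discarded), a polynomial of ``detrend_order`` is fitted per window, and
    F(n) is the RMS of the residuals pooled over all windows.  ``alpha`` is
    the least-squares slope of log F(n) vs log n over ``fit_range``
    (default: all usable scales).
    """
    if isinstance(series, CouplingTimeSeries):
        x = series.valid_values()
    else:
        x = np.asarray(series, dtype=float)
        x = x[np.isfinite(x)]
    n = x.size
    if scales is None:
        scales = default_dfa_scales(n)
    scales = np.unique(np.asarray(scales, dtype=int))
    floor = max(4, detrend_order + 2)
    usable = scales[(scales >= floor) & (scales <= n // 4)]
    dropped = scales.size - usable.size
    if dropped:
        log.warning("dropped %d DFA scales outside [%d, %d]", dropped, floor, n // 4)
    if usable.size < 4:
        raise ValueError(f"only {usable.size} usable DFA scales; need at least 4")

    profile = np.cumsum(x - x.mean())
    fn = np.empty(usable.size)
    for i, s in enumerate(usable):
        n_seg = n // s
        t = np.arange(s, dtype=float)
        vand = np.vander(t, detrend_order + 1)
        hat = vand @ np.linalg.pinv(vand)
        sq = 0.0
        for segs in (
            profile[: n_seg * s].reshape(n_seg, s),
            profile[n - n_seg * s :].reshape(n_seg, s),
        ):
            resid = segs - segs @ hat.T
            sq += float((resid**2).sum())
        fn[i] = np.sqrt(sq / (2 * n_seg * s))

    if fit_range is None:
        fit_range = (int(usable[0]), int(usable[-1]))
    in_fit = (usable >= fit_range[0]) & (usable <= fit_range[1]) & (fn > 0)
    if in_fit.sum() < 2:
        alpha = float("nan")
    else:
        alpha = float(np.polyfit(np.log(usable[in_fit]), np.log(fn[in_fit]), 1)[0])
    return DFAResult(scales=usable, fluctuation=fn, alpha=alpha,
                     fit_range=fit_range, detrend_order=detrend_order)


# ---------------------------------------------------------------------------
# magnitude-sign decomposition
# ---------------------------------------------------------------------------

@dataclass
class MagnitudeSignSeries:
    """Increments of a coupling series with their magnitude and sign parts.

    ``gap`` marks increments that would span a missing window; those are
    excluded from ``increments``/``magnitude``/``sign`` so no spurious jumps
    enter the downstream DFA.
    """

    increments: np.ndarray
    magnitude: np.ndarray
    sign: np.ndarray
    n_gaps: int = 0


def magnitude_sign(cts) -> MagnitudeSignSeries:
    """Decompose consecutive coupling increments into magnitude and sign."""
    if isinstance(cts, CouplingTimeSeries):
        vals = cts.values
    else:
        vals = np.asarray(cts, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values to form increments")
    ok = np.isfinite(vals)
    pair_ok = ok[:-1] & ok[1:]
    inc = (vals[1:] - vals[:-1])[pair_ok]
    n_gaps = int((~pair_ok).sum())
    if n_gaps:
        log.warning("%d increments span missing windows and were dropped", n_gaps)
    return MagnitudeSignSeries(
        increments=inc, magnitude=np.abs(inc), sign=np.sign(inc), n_gaps=n_gaps,
    )
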