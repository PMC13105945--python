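"""Fourier phase-randomization surrogates and link-significance thresholds.

A phase-randomized surrogate keeps the amplitude spectrum of a signal
bin-for-bin (hence every band's total power) while scrambling the Fourier
phases, destroying the temporal organisation that carries amplitude
coupling.  Link strengths computed between surrogates of *different*
participants form a null distribution; its mean and SD give the
physiological-significance threshold

    Th = mu_surr + 2 * sigma_surr.

The plain phase-randomized surrogate is spectrum-exact but Gaussianizes
the amplitude distribution; an amplitude-adjusted (AAFT) variant that
preserves the marginal distribution instead is available via ``mode``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .bandpower import BandScheme, band_power_series, make_band_scheme, zscore_global
from .config import PipelineConfig, get_logger
from .coupling import NetworkMap, coupling_matrix
from .recording import ChannelKind, Recording

__all__ = [
    "SurrogateDistribution",
    "phase_randomize",
    "surrogate_link_distribution",
    "apply_threshold",
]

log = get_logger(__name__)


def phase_randomize(rec: Recording, seed: int, mode: str = "phase") -> Recording:
    """Surrogate copy of a recording with randomized Fourier phases.

    ``mode="phase"``: amplitude spectrum preserved exactly (DC and Nyquist
    untouched, conjugate symmetry enforced by construction).
    ``mode="aaft"``: amplitude-adjusted variant — the marginal amplitude
    distribution is preserved exactly and the spectrum approximately.
    """
    if rec.n_samples < 64:
        raise ValueError("phase randomization needs at least 64 samples")
    rng = np.random.default_rng(seed)
    if mode == "phase":
        return rec.with_samples(_phase_surrogate(rec.samples, rng))
    if mode == "aaft":
        x = rec.samples
        order = np.argsort(x)
        gauss = np.sort(rng.standard_normal(x.size))
        g = np.empty_like(gauss)
        g[order] = gauss                      # Gaussianized copy with x's rank order
        gsur = _phase_surrogate(g, rng)
        out = np.empty_like(x)
        out[np.argsort(gsur)] = np.sort(x)    # re-impose the original amplitudes
        return rec.with_samples(out)
    raise ValueError(f"unknown surrogate mode {mode!r}")


def _phase_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = x.size
    spec = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, spec.size)
    out = np.abs(spec) * np.exp(1j * phases)
    out[0] = spec[0]                          # DC untouched (keeps the mean)
    if n % 2 == 0:
        out[-1] = spec[-1]                    # Nyquist bin must stay real
    return np.fft.irfft(out, n=n)


@dataclass
class SurrogateDistribution:
    """Pooled null link strengths with the significance threshold."""

    values: np.ndarray
    mu_surr: float
    sigma_surr: float
    threshold: float
    n_participant_pairs: int = 0
    n_system_pairs: int = 0
    n_links: int = 0

    @classmethod
    def from_values(cls, values, n_participant_pairs=0, n_system_pairs=0, n_links=0):
        values = np.asarray(values, dtype=float)
        mu = float(values.mean())
        sigma = float(values.std())
        return cls(values=values, mu_surr=mu, sigma_surr=sigma,
                   threshold=mu + 2 * sigma,
                   n_participant_pairs=n_participant_pairs,
                   n_system_pairs=n_system_pairs, n_links=n_links)


def _emg_channels(participant) -> dict[str, Recording]:
    if isinstance(participant, dict):
        recs = participant.values()
    else:
        recs = participant
    return {r.channel_id: r for r in recs if r.kind == ChannelKind.EMG}


def surrogate_link_distribution(
    cohort: list,
    config: PipelineConfig | None = None,
    seed: int = 0,
    mode: str = "phase",
) -> SurrogateDistribution:
    """Null link-strength distribution from cross-participant surrogate pairs.

    For every unordered pair of participants (exhaustive enumeration: 35
    participants give 595 pairs) and every muscle pair, coupling is computed
    between the phase-randomized, band-power-processed EMG of the two
    *different* participants; all link strengths are pooled and the
    threshold Th = mu + 2*sigma derived.
    """
    if len(cohort) < 2:
        raise ValueError("surrogate pairing needs at least 2 participants")
    config = config or PipelineConfig()
    scheme = make_band_scheme(config.band_low, config.band_width, config.band_count,
                              config.bin_width, config.exclusions)
    sseq = np.random.SeedSequence(seed)

    # surrogate + band power once per (participant, channel)
    bp: list[dict[str, list]] = []
    channel_names: list[str] | None = None
    for participant in cohort:
        chans = _emg_channels(participant)
        if channel_names is None:
            channel_names = sorted(chans)
        elif sorted(chans) != channel_names:
            raise ValueError("all participants must share the same EMG channel set")
        entry = {}
        for name in channel_names:
            child = sseq.spawn(1)[0]
            sur = phase_randomize(chans[name], seed=child.generate_state(1)[0], mode=mode)
            series = [zscore_global(s) for s in band_power_series(
                sur, scheme, window=config.bp_window, step=config.bp_step,
                taper=config.taper)]
            entry[name] = series
        bp.append(entry)

    muscle_pairs = list(itertools.combinations(channel_names, 2))
    part_pairs = list(itertools.combinations(range(len(cohort)), 2))
    pooled = []
    for p, q in part_pairs:
        for ch_a, ch_b in muscle_pairs:
            mat = coupling_matrix(bp[p][ch_a], bp[q][ch_b], lag=config.lag)
            pooled.append(mat.values.ravel())
    values = np.concatenate(pooled)
    n_links = scheme.n_bands**2
    log.info("pooled %d surrogate link values (%d participant pairs x %d muscle "
             "pairs x %d links)", values.size, len(part_pairs), len(muscle_pairs), n_links)
    return SurrogateDistribution.from_values(
        values, n_participant_pairs=len(part_pairs),
        n_system_pairs=len(muscle_pairs), n_links=n_links,
    )


def apply_threshold(network: NetworkMap, th: float) -> NetworkMap:
    """Flag links at or below the significance threshold (kept, not deleted)."""
    if not (0 <= th <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    links = [
        type(l)(source=l.source, target=l.target, strength=l.strength,
                class_label=l.class_label, significant=l.strength > th)
        for l in network.links
    ]
    return NetworkMap(nodes=list(network.nodes), links=links,
                      class_thresholds=network.class_thresholds,
                      class_labels=network.class_labels)
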