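"""Seeded synthetic cohorts with known ground-truth coupling.

The generator emulates the three signal classes the analysis consumes:

* **EMG** — a sum over the ten analysis bands of band-limited Gaussian
  noise, each band multiplied by a slow positive power envelope.  The
  envelope is log-normal, ``E = exp(a*z - a^2/2)`` with ``z`` a slow latent
  Gaussian process (low-pass bandwidth ~0.25 Hz, the timescale of a squat
  cycle).  Latents of the same band are correlated across channels through
  a Cholesky mixture; the latent correlation is solved analytically so the
  *envelope* correlation equals the designed rho exactly.
* **EKG** — a stylized biphasic QRS pulse train whose beat times integrate
  a programmable instantaneous heart-rate profile, plus additive noise;
  the true beat times are returned alongside.
* **Respiration** — a phase-integrated quasi-sinusoid with slow amplitude
  jitter following a programmable breathing-rate profile.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal

from .bandpower import BandScheme, make_band_scheme
from .config import get_logger
from .rates import PeakTrain
from .recording import ChannelKind, Recording

__all__ = ["SynthSpec", "CohortBundle", "synth_emg", "synth_ekg", "synth_resp",
           "synth_cohort", "write_cohort"]

log = get_logger(__name__)

LATENT_RATE = 10.0  # Hz; envelopes live well below 1 Hz


def _linear_profile(start: float, end: float, duration: float) -> Callable[[np.ndarray], np.ndarray]:
    def profile(t: np.ndarray) -> np.ndarray:
        return start + (end - start) * np.clip(t / duration, 0, 1)
    return profile


@dataclass
class SynthSpec:
    """Design of a synthetic cohort.

    ``rho_same``/``rho_cross`` set the designed same-band envelope
    correlation for same-type (LegL-LegR, BackL-BackR) and different-type
    muscle pairs; ``channel_rho`` may instead give an explicit
    channels x channels matrix.  ``envelope_log_sigma`` is the log-normal
    modulation depth ``a`` (a=1 gives power-envelope CV ~ 1.3, deep
    task-like modulation); ``envelope_bandwidth`` the latent low-pass
    cutoff in Hz.  Heart/breathing rates follow linear ramps between the
    given endpoints unless explicit profiles (callables of t seconds) are
    supplied.
    """

    n_participants: int = 5
    duration: float = 600.0
    rate: float = 1000.0
    emg_channels: tuple[str, ...] = ("LegL", "LegR", "BackL", "BackR")
    rho_same: float = 0.6
    rho_cross: float = 0.2
    channel_rho: np.ndarray | None = None
    envelope_bandwidth: float = 0.25
    envelope_log_sigma: float = 1.0
    band_weights: tuple[float, ...] | None = None
    noise_floor: float = 0.01
    hr_start: float = 75.0
    hr_end: float = 95.0
    hr_profile: Callable | None = None
    ekg_snr_db: float = 20.0
    br_start: float = 15.0
    br_end: float = 18.0
    br_profile: Callable | None = None
    seed: int = 0
    # band scheme parameters (defaults match the analysis scheme)
    band_low: float = 10.0
    band_width: float = 19.5
    band_count: int = 10
    bin_width: float = 0.5
    exclusions: tuple[tuple[float, float], ...] = ((50.0, 65.0),)

    def scheme(self) -> BandScheme:
        return make_band_scheme(self.band_low, self.band_width, self.band_count,
                                self.bin_width, self.exclusions, nyquist=self.rate / 2)

    def rho_matrix(self) -> np.ndarray:
        """Designed envelope correlation between channels (same band)."""
        if self.channel_rho is not None:
            rho = np.asarray(self.channel_rho, dtype=float)
            if rho.shape != (len(self.emg_channels),) * 2:
                raise ValueError("channel_rho must be channels x channels")
            return rho
        names = self.emg_channels
        n = len(names)
        rho = np.full((n, n), self.rho_cross)
        for i in range(n):
            for j in range(n):
                same_type = names[i].rstrip("LR") == names[j].rstrip("LR")
                if same_type and i != j:
                    rho[i, j] = self.rho_same
        np.fill_diagonal(rho, 1.0)
        return rho

    def latent_rho_matrix(self) -> np.ndarray:
        """Latent Gaussian correlation reproducing the designed log-normal
        envelope correlation: rho_z = ln(1 + rho*(e^{a^2}-1)) / a^2."""
        a2 = self.envelope_log_sigma**2
        rho = self.rho_matrix()
        if np.abs(rho).max() > 1:
            raise ValueError("envelope correlations must lie in [-1, 1]")
        arg = 1 + rho * np.expm1(a2)
        if (arg <= 0).any():
            raise ValueError("designed rho too negative for the log-normal envelope model")
        rho_z = np.log(arg) / a2
        np.fill_diagonal(rho_z, 1.0)
        return rho_z

    def hr(self, t: np.ndarray) -> np.ndarray:
        f = self.hr_profile or _linear_profile(self.hr_start, self.hr_end, self.duration)
        return np.asarray(f(t), dtype=float)

    def br(self, t: np.ndarray) -> np.ndarray:
        f = self.br_profile or _linear_profile(self.br_start, self.br_end, self.duration)
        return np.asarray(f(t), dtype=float)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def _slow_process(rng: np.random.Generator, n: int, fs: float, cutoff: float) -> np.ndarray:
    """Unit-variance low-pass Gaussian process.

    Generated with burn-in margins of several filter time constants on both
    sides, which are discarded, so no start-up transient leaks into the
    returned samples.
    """
    pad = int(round(10 * fs / cutoff))
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    z = signal.sosfilt(sos, rng.standard_normal(n + 2 * pad))[pad: pad + n]
    return (z - z.mean()) / z.std()


def _band_envelopes(spec: SynthSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Latent-rate power envelopes for every (channel, band).

    Returns (t_lat, env) with env of shape (n_channels, n_bands, n_lat).
    The same participant ``seed`` always reproduces the same shared latent
    processes, so channels generated one at a time remain jointly coupled.
    """
    scheme = spec.scheme()
    n_ch = len(spec.emg_channels)
    n_lat = int(round(spec.duration * LATENT_RATE))
    chol = np.linalg.cholesky(spec.latent_rho_matrix())  # raises if not PSD
    a = spec.envelope_log_sigma
    env = np.empty((n_ch, scheme.n_bands, n_lat))
    for b in range(scheme.n_bands):
        base = np.stack([
            _slow_process(_rng(seed, 0, b, j), n_lat, LATENT_RATE, spec.envelope_bandwidth)
            for j in range(n_ch)
        ])
        latents = chol @ base
        env[:, b, :] = np.exp(a * latents - a**2 / 2)
    t_lat = np.arange(n_lat) / LATENT_RATE
    return t_lat, env


def synth_emg(spec: SynthSpec, channel: str, seed: int) -> Recording:
    """One synthetic EMG channel of a participant keyed by ``seed``.

    Calling this for every channel with the *same* participant seed yields
    the designed cross-channel envelope correlations.
    """
    samples, _ = _synth_emg_samples(spec, channel, seed)
    return Recording(channel_id=channel, kind=ChannelKind.EMG, samples=samples,
                     rate=spec.rate)


def _synth_emg_samples(spec: SynthSpec, channel: str, seed: int) -> tuple[np.ndarray, np.ndarray]:
    scheme = spec.scheme()
    if scheme.bands[-1].high >= spec.rate / 2:
        raise ValueError("band edges must stay below Nyquist")
    try:
        c = spec.emg_channels.index(channel)
    except ValueError:
        raise ValueError(f"unknown channel {channel!r}; spec has {spec.emg_channels}") from None
    weights = np.asarray(spec.band_weights if spec.band_weights is not None
                         else np.ones(scheme.n_bands), dtype=float)
    if weights.shape != (scheme.n_bands,):
        raise ValueError("band_weights must have one entry per band")

    t_lat, env_all = _band_envelopes(spec, seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    out = np.zeros(n)
    for b, band in enumerate(scheme.bands):
        if weights[b] == 0:
            continue
        rng = _rng(seed, 1, c, b)
        sos = signal.butter(4, (band.low, band.high), btype="bandpass",
                            fs=spec.rate, output="sos")
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= carrier.std()
        env = np.interp(t, t_lat, env_all[c, b])
        out += np.sqrt(weights[b] * env) * carrier
    if spec.noise_floor > 0:
        rng = _rng(seed, 2, c)
        out += np.sqrt(spec.noise_floor * weights.sum()) * rng.standard_normal(n)
    return out, env_all[c]


def synth_ekg(spec: SynthSpec, seed: int) -> tuple[Recording, PeakTrain]:
    """Synthetic EKG following the spec's heart-rate profile, plus true beats."""
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    hr = spec.hr(t)
    if hr.min() < 25 or hr.max() > 250:
        raise ValueError("hr profile must stay within [25, 250] BPM")
    phase = np.cumsum(hr / 60.0) / spec.rate    # beats elapsed
    targets = np.arange(0.5, phase[-1], 1.0)    # first beat half an RR in
    beat_times = np.interp(targets, phase, t)
    beat_idx = np.round(beat_times * spec.rate).astype(int)
    beat_idx = beat_idx[(beat_idx >= 0) & (beat_idx < n)]

    # stylized biphasic QRS: dominant R wave with symmetric Q/S dips
    half = int(round(0.05 * spec.rate))
    tau = np.arange(-half, half + 1) / spec.rate
    template = (np.exp(-(tau**2) / (2 * 0.008**2))
                - 0.2 * np.exp(-((tau - 0.018) ** 2) / (2 * 0.006**2))
                - 0.2 * np.exp(-((tau + 0.018) ** 2) / (2 * 0.006**2)))
    x = np.zeros(n)
    for idx in beat_idx:
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        x[lo:hi] += template[half - (idx - lo): half + (hi - idx)]
    rms = np.sqrt(np.mean(x**2))
    noise_sd = rms * 10 ** (-spec.ekg_snr_db / 20)
    x += _rng(seed, 3).standard_normal(n) * noise_sd
    rec = Recording(channel_id="EKG", kind=ChannelKind.EKG, samples=x, rate=spec.rate)
    return rec, PeakTrain(peak_times=beat_idx / spec.rate)


def synth_resp(spec: SynthSpec, seed: int) -> Recording:
    """Quasi-sinusoidal respiratory-belt signal following the BR profile."""
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    br = spec.br(t)
    if br.min() < 4 or br.max() > 80:
        raise ValueError("br profile must stay within [4, 80] breaths/min")
    phase = 2 * np.pi * np.cumsum(br / 60.0) / spec.rate
    n_lat = int(round(spec.duration * LATENT_RATE))
    jitter = _slow_process(_rng(seed, 4), n_lat, LATENT_RATE, 0.05)
    amp = 1.0 + 0.1 * np.interp(t, np.arange(n_lat) / LATENT_RATE, jitter)
    x = amp * np.sin(phase) + 0.01 * _rng(seed, 5).standard_normal(n)
    return Recording(channel_id="Resp", kind=ChannelKind.RESP, samples=x, rate=spec.rate)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Synthetic participants plus their ground-truth tables."""

    spec: SynthSpec
    participants: list[dict[str, Recording]]
    ekg_truth: list[PeakTrain]
    truth: pd.DataFrame                 # designed & measured envelope correlations
    participant_seeds: list[int] = field(default_factory=list)


def synth_cohort(spec: SynthSpec) -> CohortBundle:
    """Generate the full cohort (4 EMG + 1 EKG + 1 resp per participant).

    The truth table records, per participant, channel pair and band, the
    designed envelope correlation, the latent correlation used to realise
    it, and the correlation actually measured between the generated
    (latent-rate) envelopes.
    """
    root = np.random.SeedSequence(spec.seed)
    part_seeds = [int(s) for s in root.generate_state(spec.n_participants)]
    scheme = spec.scheme()
    rho = spec.rho_matrix()
    rho_z = spec.latent_rho_matrix()

    participants: list[dict[str, Recording]] = []
    ekg_truth: list[PeakTrain] = []
    rows = []
    for p, pseed in enumerate(part_seeds):
        chans: dict[str, Recording] = {}
        envs = {}
        for name in spec.emg_channels:
            samples, env = _synth_emg_samples(spec, name, pseed)
            chans[name] = Recording(channel_id=name, kind=ChannelKind.EMG,
                                    samples=samples, rate=spec.rate)
            envs[name] = env
        ekg, truth_train = synth_ekg(spec, pseed)
        chans["EKG"] = ekg
        chans["Resp"] = synth_resp(spec, pseed)
        participants.append(chans)
        ekg_truth.append(truth_train)
        for i, a in enumerate(spec.emg_channels):
            for j in range(i + 1, len(spec.emg_channels)):
                b = spec.emg_channels[j]
                for bi, band in enumerate(scheme.bands):
                    measured = float(np.corrcoef(envs[a][bi], envs[b][bi])[0, 1])
                    rows.append({
                        "participant": p, "channel_a": a, "channel_b": b,
                        "band": band.label, "designed_rho": float(rho[i, j]),
                        "latent_rho": float(rho_z[i, j]), "measured_env_corr": measured,
                    })
    truth = pd.DataFrame(rows)
    return CohortBundle(spec=spec, participants=participants, ekg_truth=ekg_truth,
                        truth=truth, participant_seeds=part_seeds)


def write_cohort(bundle: CohortBundle, out_dir) -> list:
    """Write every participant as CSV + sidecar, plus ``truth.csv``."""
    from pathlib import Path

    from .io import write_recordings

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p, chans in enumerate(bundle.participants):
        path = write_recordings(list(chans.values()), out_dir / f"participant{p:02d}.csv")
        paths.append(path)
    bundle.truth.to_csv(out_dir / "truth.csv", index=False)
    paths.append(out_dir / "truth.csv")
    return paths
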