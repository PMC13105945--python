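"""Signal conditioning: zero-phase band-pass and mains-notch filtering.

EMG is band-passed 5-250 Hz and EKG 0.5-150 Hz by default; a 1-Hz-wide
band-stop centred on the mains frequency (60 Hz, or 50 Hz on European
grids) removes power-line interference.  Filters are 4th-order Butterworth
designs applied forward-backward (``sosfiltfilt``) so the output is
zero-phase — a requirement for the zero-lag coupling analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import signal

from .recording import Recording

__all__ = ["FilterSpec", "bandpass", "notch", "preprocess_recording"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass corner frequencies plus notch settings, all in Hz."""

    low_cut: float
    high_cut: float
    notch_center: float = 60.0
    notch_width: float = 1.0
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.low_cut < self.high_cut):
            raise ValueError("need 0 <= low_cut < high_cut")
        if self.notch_width <= 0:
            raise ValueError("notch_width must be > 0")


def _apply_sos(rec: Recording, sos) -> Recording:
    # reflect padding avoids startup transients in short segments
    padlen = min(rec.n_samples - 1, 3 * (2 * len(sos) + 1) * 10)
    out = signal.sosfiltfilt(sos, rec.samples, padtype="even", padlen=padlen)
    return rec.with_samples(out)


def bandpass(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase Butterworth band-pass of ``spec.order`` (length preserved)."""
    nyq = rec.rate / 2
    if spec.high_cut >= nyq:
        raise ValueError(
            f"high_cut {spec.high_cut} Hz must be below the Nyquist frequency {nyq} Hz"
        )
    if spec.low_cut <= 0:
        sos = signal.butter(spec.order, spec.high_cut, btype="lowpass", fs=rec.rate, output="sos")
    else:
        sos = signal.butter(spec.order, (spec.low_cut, spec.high_cut), btype="bandpass",
                            fs=rec.rate, output="sos")
    return _apply_sos(rec, sos)


def notch(rec: Recording, center: float, width: float = 1.0, order: int = 4) -> Recording:
    """Zero-phase band-stop of the stated width centred on ``center`` Hz."""
    nyq = rec.rate / 2
    if center >= nyq:
        raise ValueError(f"notch center {center} Hz must be below Nyquist {nyq} Hz")
    lo, hi = center - width / 2, center + width / 2
    sos = signal.butter(order, (lo, hi), btype="bandstop", fs=rec.rate, output="sos")
    return _apply_sos(rec, sos)


def preprocess_recording(
    rec: Recording,
    emg_band: tuple[float, float] = (5.0, 250.0),
    ekg_band: tuple[float, float] = (0.5, 150.0),
    notch_center: float = 60.0,
    notch_width: float = 1.0,
    order: int = 4,
) -> Recording:
    """Apply the kind-appropriate band-pass plus the mains notch.

    EMG and EKG get band-pass + notch; respiratory-belt channels are only
    low-passed below 5 Hz (respiration lives well under 1 Hz).
    """
    if rec.kind.value == "emg":
        band = emg_band
    elif rec.kind.value == "ekg":
        band = ekg_band
    else:
        sos = signal.butter(order, 5.0, btype="lowpass", fs=rec.rate, output="sos")
        return _apply_sos(rec, sos)
    spec = FilterSpec(band[0], band[1], notch_center, notch_width, order)
    return notch(bandpass(rec, spec), notch_center, notch_width, order)
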