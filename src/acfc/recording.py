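"""Core in-memory data model for multichannel physiological recordings.

A :class:`Recording` holds one uniformly sampled channel (EMG, EKG or a
respiratory belt).  All downstream stages exchange the small dataclasses
defined here rather than bare arrays so that sampling rate, channel kind
and time origin travel with the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = ["ChannelKind", "Recording", "SegmentLabel"]


class ChannelKind(str, Enum):
    """What a channel records: surface EMG, EKG, or respiratory effort."""

    EMG = "emg"
    EKG = "ekg"
    RESP = "resp"


@dataclass
class Recording:
    """One uniformly sampled channel.

    Parameters
    ----------
    channel_id : str
        Name of the channel (e.g. ``"LegL"``).
    kind : ChannelKind or str
        ``emg``, ``ekg`` or ``resp``.
    samples : ndarray
        Signal values in arbitrary units; must be finite and non-empty.
    rate : float
        Sampling rate in samples/second, > 0.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    channel_id: str
    kind: ChannelKind
    samples: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.kind = ChannelKind(self.kind)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError(f"channel {self.channel_id!r}: samples must be a non-empty 1-D array")
        if not np.isfinite(self.samples).all():
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(
                f"channel {self.channel_id!r}: non-finite sample at index {bad}"
            )
        if not self.rate > 0:
            raise ValueError(f"channel {self.channel_id!r}: rate must be > 0, got {self.rate}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / rate)."""
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds from recording start."""
        return self.start_time + np.arange(self.n_samples) / self.rate

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with new sample values (rate/kind preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def crop(self, start: float, end: float) -> "Recording":
        """Return the sub-recording covering [start, end) seconds."""
        if not start < end:
            raise ValueError("crop requires start < end")
        i0 = max(0, int(np.ceil((start - self.start_time) * self.rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((end - self.start_time) * self.rate - 1e-9)))
        if i1 <= i0:
            raise ValueError("crop window does not overlap the recording")
        return Recording(
            channel_id=self.channel_id,
            kind=self.kind,
            samples=self.samples[i0:i1].copy(),
            rate=self.rate,
            start_time=self.start_time + i0 / self.rate,
        )


@dataclass(frozen=True)
class SegmentLabel:
    """A named protocol segment, e.g. Rest or Exercise, in seconds."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"segment {self.name!r}: need 0 <= start < end")

    @property
    def duration(self) -> float:
        return self.end - self.start
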