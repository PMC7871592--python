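"""Core containers for multichannel field-potential data.

The central object is :class:`MultiChannelRecording`: a channels x samples
array of extracellular voltage (conventionally microvolts) sampled uniformly,
with one region label per channel and a declared recording reference.  All
metric modules consume either this container or the band-limited
:class:`AnalyticSignal` derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MultiChannelRecording",
    "BandSpec",
    "AnalyticSignal",
    "SegmentSet",
    "DEFAULT_BANDS",
]


@dataclass
class BandSpec:
    """A named frequency band, edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band edges must satisfy 0 < lo < hi, got {self.lo}, {self.hi}")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo) & (freqs <= self.hi)


#: Canonical bands: delta 1-4, theta 5-12, beta 15-30, low gamma 30-48 Hz.
DEFAULT_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 5.0, 12.0),
    "beta": BandSpec("beta", 15.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 48.0),
}


@dataclass
class MultiChannelRecording:
    """Uniformly sampled multichannel voltage traces with region labels.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), voltage in microvolts.
    rate_hz
        Sampling rate in samples per second.
    labels
        One region label per channel; must be unique.
    reference
        Label of the subtracted reference ("ground" by default).
    """

    data: np.ndarray
    rate_hz: float
    labels: Sequence[str]
    reference: str = "ground"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D trace for a labelled channel."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}; have {self.labels}") from None
        return self.data[idx]

    def copy_with(self, **kw) -> "MultiChannelRecording":
        return replace(self, **kw)


@dataclass
class AnalyticSignal:
    """Instantaneous amplitude and phase of a band-limited signal.

    Phase convention: radians wrapped to (-pi, pi], zero at the positive peak
    of a cosine-aligned oscillation (``angle(hilbert(cos))=0``).
    """

    amplitude: np.ndarray
    phase: np.ndarray
    band: BandSpec
    rate_hz: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must have equal shapes")


@dataclass
class SegmentSet:
    """Equal-length analysis windows over a record.

    Windows are half-open sample ranges [start, start + length); ``pad_to``
    is the FFT length after zero padding (next power of two when requested).
    """

    starts: np.ndarray
    length: int
    overlap: float
    pad_to: int
    rate_hz: float

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        if self.pad_to < self.length:
            raise ValueError("pad_to must be >= window length")

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def slices(self):
        for s in self.starts:
            yield slice(int(s), int(s) + self.length)
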