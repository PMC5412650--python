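"""Core data model: uniformly sampled channels, event series, recordings.

All times are in seconds with t = 0 at recording start; events live in
recording time, never in sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "EventSeries",
    "Recording",
    "HemopulseError",
    "FormatError",
    "ParseError",
    "ConfigError",
    "DataError",
    "ParameterError",
    "PairingError",
    "CalibrationError",
    "GeometryError",
]


class HemopulseError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HemopulseError):
    """A file or container violates the recording format contract."""


class ParseError(HemopulseError):
    """A file contains unparseable content (carries line context)."""


class ConfigError(HemopulseError):
    """Invalid configuration (overlapping holds, missing channels, ...)."""


class DataError(HemopulseError):
    """Data values violate a precondition (e.g. nonpositive intensity)."""


class ParameterError(HemopulseError):
    """Invalid analysis parameter (e.g. cutoff above Nyquist)."""


class PairingError(HemopulseError):
    """Beat matching between two event series failed."""


class CalibrationError(HemopulseError):
    """PTT→BP calibration fit is invalid (non-monotone, degenerate)."""


class GeometryError(HemopulseError):
    """NIRS geometry is unusable (singular extinction matrix, ...)."""


@dataclass
class TimeSeries:
    """One uniformly sampled channel.

    Parameters
    ----------
    data : ndarray
        Sample values in ``units``.
    rate : float
        Sampling rate in Hz; must be positive.
    start : float
        Time of the first sample in seconds.
    label : str
        Channel name.
    units : str
        Physical units of the samples (free text).
    """

    data: np.ndarray
    rate: float
    start: float = 0.0
    label: str = ""
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1 or self.data.size < 1:
            raise FormatError(f"channel {self.label!r}: data must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.data)):
            raise FormatError(f"channel {self.label!r}: samples must be finite")
        if not (self.rate > 0):
            raise FormatError(f"channel {self.label!r}: sampling rate must be > 0, got {self.rate}")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, ``n / rate`` seconds."""
        return self.n / self.rate

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.n) / self.rate

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "TimeSeries":
        """Return a copy, optionally replacing samples and metadata."""
        out = dict(data=self.data.copy() if data is None else np.asarray(data, float),
                   rate=self.rate, start=self.start, label=self.label, units=self.units)
        out.update(kw)
        return TimeSeries(**out)

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the span)."""
        i = int(round((t - self.start) * self.rate))
        return min(max(i, 0), self.n - 1)

    def slice(self, tmin: float, tmax: float) -> "TimeSeries":
        """Samples with times in ``[tmin, tmax)``."""
        i0 = max(int(np.ceil((tmin - self.start) * self.rate - 1e-9)), 0)
        i1 = min(int(np.ceil((tmax - self.start) * self.rate - 1e-9)), self.n)
        if i1 <= i0:
            raise ParameterError(f"empty slice [{tmin}, {tmax}) of channel {self.label!r}")
        return TimeSeries(self.data[i0:i1], self.rate, self.start + i0 / self.rate,
                          self.label, self.units)


@dataclass
class EventSeries:
    """Strictly increasing event times (beats, stimulus markers)."""

    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise FormatError(f"events {self.label!r}: times must be strictly increasing")
        if self.times.size and not np.all(np.isfinite(self.times)):
            raise FormatError(f"events {self.label!r}: times must be finite")

    @property
    def n(self) -> int:
        return self.times.size

    def __len__(self) -> int:
        return self.n

    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class Recording:
    """A named collection of channels plus marker series and metadata.

    Channels may have different rates but must cover a common span
    (starts equal, durations equal within one sample period of the
    slowest channel).
    """

    channels: dict[str, TimeSeries] = field(default_factory=dict)
    markers: dict[str, EventSeries] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, ch in self.channels.items():
            if ch.label != label:
                ch.label = label
        self.validate()

    def validate(self) -> None:
        if not self.channels:
            return
        starts = {ch.start for ch in self.channels.values()}
        if len(starts) > 1:
            raise FormatError(f"channels must share a start time, got {sorted(starts)}")
        tol = max(1.0 / ch.rate for ch in self.channels.values())
        durs = [ch.duration for ch in self.channels.values()]
        if max(durs) - min(durs) > tol + 1e-9:
            raise FormatError(
                "channels must cover a common span within one sample period; "
                f"durations range {min(durs):.6f}–{max(durs):.6f} s, tolerance {tol:.6f} s")

    @property
    def duration(self) -> float:
        return max(ch.duration for ch in self.channels.values()) if self.channels else 0.0

    def channel(self, label: str) -> TimeSeries:
        try:
            return self.channels[label]
        except KeyError:
            raise ConfigError(
                f"channel {label!r} not in recording (has: {sorted(self.channels)})") from None

    def add_channel(self, ts: TimeSeries) -> None:
        if ts.label in self.channels:
            raise FormatError(f"duplicate channel label {ts.label!r}")
        self.channels[ts.label] = ts
        self.validate()

    def add_markers(self, ev: EventSeries) -> None:
        if ev.label in self.markers:
            raise FormatError(f"duplicate marker label {ev.label!r}")
        if ev.n and self.channels:
            if ev.times[0] < 0 or ev.times[-1] > self.duration:
                raise FormatError(
                    f"marker {ev.label!r} outside recording span [0, {self.duration:.3f}] s")
        self.markers[ev.label] = ev
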