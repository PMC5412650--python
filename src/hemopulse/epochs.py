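"""Band-pass presets, event-locked epoching and across-repeat averaging.

The breath-hold analysis epochs every derived series from 5 s before
each hold onset to 80 s after it, subtracts each epoch's own
whole-interval mean (baseline correction) and averages across repeats,
reporting the pointwise mean and standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import EventSeries, ParameterError, TimeSeries
from .filtering import zero_phase_filter

__all__ = ["EpochSet", "AveragedResponse", "bandpass", "epoch",
           "beat_series_to_timeseries", "baseline_correct", "average_epochs"]


@dataclass
class EpochSet:
    """Event-locked segments on a shared relative time axis."""

    data: np.ndarray        # (n_events, n_samples)
    times: np.ndarray       # s relative to event onset; includes 0
    label: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        self.times = np.asarray(self.times, float)
        if self.data.shape[1] != self.times.size:
            raise ParameterError("epoch matrix and time axis disagree")
        if self.times.size and not (self.times[0] <= 0 <= self.times[-1]):
            raise ParameterError("epoch time axis must include the event onset (t = 0)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class AveragedResponse:
    """Pointwise mean ± SD across epochs (sample SD, n−1 denominator)."""

    mean: np.ndarray
    sd: np.ndarray
    n: int
    times: np.ndarray
    label: str = ""


def bandpass(ts: TimeSeries, low: float, high: float, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass preset.

    ``low = 0`` degenerates to a low-pass, ``high = inf`` to a
    high-pass (e.g. the 0.01 Hz high-pass used before averaging).
    """
    out = zero_phase_filter(ts.data, ts.rate, low, high, order=order)
    return ts.copy_with(data=out)


def beat_series_to_timeseries(times: np.ndarray, values: np.ndarray,
                              rate: float = 4.0, start: float | None = None,
                              end: float | None = None, label: str = "",
                              units: str = "a.u.") -> TimeSeries:
    """Linear interpolation of an irregular per-beat series onto a
    uniform grid, so it can be epoched like any channel."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size < 2:
        raise ParameterError("need at least two per-beat samples to resample")
    t0 = times[0] if start is None else start
    t1 = times[-1] if end is None else end
    grid = np.arange(t0, t1 + 0.5 / rate, 1.0 / rate)
    return TimeSeries(np.interp(grid, times, values), rate=rate, start=t0,
                      label=label, units=units)


def epoch(ts: TimeSeries, events: EventSeries, tmin: float = -5.0,
          tmax: float = 80.0) -> EpochSet:
    """Cut one fixed window per event, time-locked to the event onset.

    Events whose window extends past the recording are dropped with a
    warning rather than zero-padded.
    """
    if not (tmin <= 0 <= tmax) or tmin == tmax:
        raise ParameterError(f"window ({tmin}, {tmax}) must bracket the onset")
    n_rel = int(round((tmax - tmin) * ts.rate)) + 1
    rel = tmin + np.arange(n_rel) / ts.rate
    rows, dropped = [], 0
    for ev in events.times:
        i0 = int(round((ev + tmin - ts.start) * ts.rate))
        if i0 < 0 or i0 + n_rel > ts.n:
            dropped += 1
            continue
        rows.append(ts.data[i0:i0 + n_rel])
    if dropped:
        warnings.warn(f"dropped {dropped} epoch(s) extending past the recording",
                      stacklevel=2)
    if not rows:
        raise ParameterError("no event window fits inside the recording")
    return EpochSet(np.vstack(rows), rel, label=ts.label, n_dropped=dropped)


def baseline_correct(es: EpochSet, mode: str = "whole_interval_mean") -> EpochSet:
    """Subtract each epoch's mean over the whole interval (idempotent)."""
    if mode != "whole_interval_mean":
        raise ParameterError(f"unknown baseline mode {mode!r}")
    data = es.data - es.data.mean(axis=1, keepdims=True)
    return EpochSet(data, es.times.copy(), label=es.label, n_dropped=es.n_dropped)


def average_epochs(es: EpochSet, include: np.ndarray | None = None) -> AveragedResponse:
    """Pointwise mean and sample SD across (optionally masked) epochs."""
    data = es.data if include is None else es.data[np.asarray(include, bool)]
    if data.shape[0] < 1:
        raise ParameterError("no epochs selected for averaging")
    n = data.shape[0]
    sd = data.std(axis=0, ddof=1) if n > 1 else np.zeros(data.shape[1])
    return AveragedResponse(mean=data.mean(axis=0), sd=sd, n=n,
                            times=es.times.copy(), label=es.label)
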