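"""Heart-beat detection on accelerometer and MEG channels.

Two-stage, reference-guided scheme: the channel with the clearest
pulse (typically the chest accelerometer, or a cardiac-artifact MEG
channel) is scanned for free-running peaks; every other channel is
then searched only inside a per-beat lag window anchored to those
reference beats, taking the in-window maximum. The manual visual
sanity check of detected beats is replaced by automatic interval-based
QC (median ± k·MAD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import EventSeries, ParameterError, TimeSeries
from .filtering import zero_phase_filter

__all__ = ["PeakDetectionParams", "GuidedPeaks", "BeatQCReport",
           "detect_reference_peaks", "detect_peaks_guided", "qc_beat_series"]


@dataclass
class PeakDetectionParams:
    """Knobs of both detectors.

    ``lag_min``/``lag_max`` bound the guided search window relative to
    each reference beat; the defaults (20–400 ms) span physiological
    chest→neck transit times. ``smoothing_bandwidth`` is an optional
    zero-phase low-pass applied before peak picking; ``highpass``
    additionally removes slow baseline (respiration) for free-running
    detection.
    """

    min_interval: float = 0.3          # s, refractory period
    lag_min: float = 0.02              # s, guided window start
    lag_max: float = 0.4               # s, guided window end
    polarity: str = "positive"         # positive | negative | absolute
    smoothing_bandwidth: float | None = 20.0   # Hz low-pass, None = off
    highpass: float | None = None      # Hz, None = off
    threshold_window: float = 10.0     # s, rolling-percentile span
    threshold_percentile: float = 95.0
    threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_interval <= 0:
            raise ParameterError("min_interval must be > 0")
        if not (self.lag_max > self.lag_min):
            raise ParameterError("lag window must satisfy lag_min < lag_max")
        if self.polarity not in ("positive", "negative", "absolute"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")


def _oriented(data: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "negative":
        return -data
    if polarity == "absolute":
        return np.abs(data)
    return data


def _preprocess(ts: TimeSeries, params: PeakDetectionParams) -> np.ndarray:
    x = ts.data
    if params.highpass or params.smoothing_bandwidth:
        x = zero_phase_filter(x, ts.rate, params.highpass, params.smoothing_bandwidth)
    return _oriented(x, params.polarity)


def _rolling_stat(x: np.ndarray, rate: float, window: float, q: float) -> np.ndarray:
    """Per-sample percentile of a centred rolling window (block interpolated)."""
    n = x.size
    win = max(int(round(window * rate)), 1)
    hop = max(win // 4, 1)
    centers = np.arange(0, n, hop)
    vals = np.empty(centers.size)
    for j, c in enumerate(centers):
        i0, i1 = max(c - win // 2, 0), min(c + win // 2 + 1, n)
        vals[j] = np.percentile(x[i0:i1], q)
    return np.interp(np.arange(n), centers, vals)


def detect_reference_peaks(ts: TimeSeries, params: PeakDetectionParams | None = None
                           ) -> EventSeries:
    """Free-running beat detection with an adaptive threshold.

    Local maxima of the (optionally filtered) signal that exceed
    ``threshold_fraction`` × rolling 95th percentile (baseline-median
    subtracted, so detection is invariant to positive affine rescaling)
    and are separated by at least ``min_interval``. A flat signal
    yields an empty series, not an error.
    """
    params = params or PeakDetectionParams()
    if ts.duration <= 2 * params.min_interval:
        raise ParameterError("signal shorter than twice the refractory period")
    x = _preprocess(ts, params)
    base = _rolling_stat(x, ts.rate, params.threshold_window, 50.0)
    x = x - base
    height = params.threshold_fraction * _rolling_stat(
        x, ts.rate, params.threshold_window, params.threshold_percentile)
    idx, _ = sps.find_peaks(x, height=height,
                            distance=max(int(round(params.min_interval * ts.rate)), 1))
    return EventSeries(ts.start + idx / ts.rate, label=f"beats_{ts.label}")


@dataclass
class GuidedPeaks:
    """Per-reference guided detections, index-aligned with the reference.

    ``times[i]`` is the detected time for reference beat ``i`` or NaN
    when that beat's search window fell outside the signal span.
    """

    times: np.ndarray
    reference: EventSeries
    label: str = ""

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.times).sum())

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.times)

    def events(self) -> EventSeries:
        """Valid detections as a strictly increasing event series.

        A detection that does not advance past its predecessor (possible
        when overlapping windows lock onto the same peak) is dropped.
        """
        t = self.times[self.valid]
        keep = np.ones(t.size, dtype=bool)
        last = -np.inf
        for i, v in enumerate(t):
            if v <= last:
                keep[i] = False
            else:
                last = v
        return EventSeries(t[keep], label=self.label)


def detect_peaks_guided(ts: TimeSeries, reference: EventSeries,
                        params: PeakDetectionParams | None = None) -> GuidedPeaks:
    """Maximum-in-interval search anchored to reference beats.

    For each reference beat the window ``[ref + lag_min, ref + lag_max]``
    is intersected with the signal span and the per-polarity argmax is
    taken; at equal maxima the earliest sample wins. Windows entirely
    outside the span mark the beat missing rather than fabricating one.
    """
    params = params or PeakDetectionParams()
    if reference.n == 0:
        raise ParameterError("reference event series is empty")
    x = _preprocess(ts, params)
    fs, t0, n = ts.rate, ts.start, ts.n
    out = np.full(reference.n, np.nan)
    for i, rt in enumerate(reference.times):
        i0 = int(np.ceil((rt + params.lag_min - t0) * fs - 1e-9))
        i1 = int(np.floor((rt + params.lag_max - t0) * fs + 1e-9)) + 1
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        out[i] = t0 + (i0 + int(np.argmax(x[i0:i1]))) / fs
    return GuidedPeaks(times=out, reference=reference, label=f"beats_{ts.label}")


@dataclass
class BeatQCReport:
    """Summary of automatic beat-series quality control."""

    n_input: int
    n_removed: int
    removed_times: np.ndarray
    n_gap_flags: int
    gap_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_removed": self.n_removed,
                "removed_times": [float(t) for t in self.removed_times],
                "n_gap_flags": self.n_gap_flags,
                "gap_times": [float(t) for t in self.gap_times]}


def qc_beat_series(events: EventSeries, min_interval: float = 0.3,
                   max_interval: float = 2.0, mad_k: float = 5.0,
                   gap_factor: float = 1.7) -> tuple[EventSeries, BeatQCReport]:
    """Remove physiologically impossible beats, flag missed-beat gaps.

    Intervals below ``min_interval`` or below ``median − k·MAD`` mark a
    spurious detection: of the two events forming such an interval, the
    one whose removal restores the local rhythm best (merged interval
    closest to the median) is dropped, iteratively. The MAD scale is
    floored at 5 % of the median interval so that slow, genuine rhythm
    wander (which keeps the raw MAD small) is never treated as
    spurious. Intervals above ``gap_factor × median`` (or
    ``max_interval``) are flagged as gaps but the bounding beats are
    kept — a missed beat cannot be invented.
    """
    times = events.times.copy()
    removed: list[float] = []
    while times.size >= 3:
        iv = np.diff(times)
        med = np.median(iv)
        mad = np.median(np.abs(iv - med))
        thr_short = max(min_interval, med - mad_k * max(mad, 0.05 * med))
        bad = np.flatnonzero(iv < thr_short)
        if bad.size == 0:
            break
        j = int(bad[0])  # events j and j+1 form the short interval
        def merged_cost(e: int) -> float:
            if e == 0 or e == times.size - 1:
                return 0.0  # boundary event: removal loses no rhythm
            return abs((times[e + 1] - times[e - 1]) - med)
        drop = j if merged_cost(j) <= merged_cost(j + 1) else j + 1
        removed.append(float(times[drop]))
        times = np.delete(times, drop)
    gap_times = np.empty(0)
    n_gaps = 0
    if times.size >= 2:
        iv = np.diff(times)
        med = np.median(iv)
        gaps = iv > min(max_interval, gap_factor * med)
        n_gaps = int(gaps.sum())
        gap_times = times[:-1][gaps]
    report = BeatQCReport(n_input=events.n, n_removed=len(removed),
                          removed_times=np.asarray(removed), n_gap_flags=n_gaps,
                          gap_times=gap_times)
    return EventSeries(times, label=events.label), report
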