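"""Respiration waveform extraction and breath-hold interval detection.

The chest accelerometer carries the breathing motion as a slow
(< 0.5 Hz) component under the cardiac pulses; a zero-phase low-pass
at 0.5 Hz recovers it. Breath holds appear as stretches where the
respiration envelope collapses; when the task provides markers those
are preferred, envelope detection is a convenience for unmarked data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import ParameterError, TimeSeries
from .filtering import zero_phase_filter

__all__ = ["BreathHoldInterval", "extract_respiration", "detect_breath_holds"]


@dataclass
class BreathHoldInterval:
    onset: float    # s
    offset: float   # s
    source: str = "detected"   # marker | detected

    def __post_init__(self) -> None:
        if not (self.offset > self.onset):
            raise ParameterError(f"hold offset {self.offset} must exceed onset {self.onset}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def extract_respiration(acm: TimeSeries, cutoff: float = 0.5, order: int = 4) -> TimeSeries:
    """Zero-phase low-pass of an accelerometer channel at ``cutoff`` Hz."""
    if acm.rate <= 2 * cutoff:
        raise ParameterError(
            f"sampling rate {acm.rate} Hz too low for a {cutoff} Hz cutoff")
    out = zero_phase_filter(acm.data, acm.rate, None, cutoff, order=order)
    return acm.copy_with(data=out, label=f"resp_{acm.label}")


def detect_breath_holds(resp: TimeSeries, min_duration: float = 10.0,
                        quiet_threshold: float = 0.25,
                        envelope_window: float = 5.0) -> list[BreathHoldInterval]:
    """Maximal quiet intervals of the respiration envelope.

    The envelope is a centred rolling SD over ``envelope_window``
    seconds; samples below ``quiet_threshold`` × the recording median
    envelope count as quiet, and maximal quiet runs of at least
    ``min_duration`` seconds are returned. An all-quiet signal yields
    one interval spanning the recording.
    """
    x = resp.data - resp.data.mean()
    win = max(int(round(envelope_window * resp.rate)), 2)
    mean = uniform_filter1d(x, win, mode="nearest")
    sq = uniform_filter1d(x * x, win, mode="nearest")
    env = np.sqrt(np.maximum(sq - mean ** 2, 0.0))
    med = np.median(env)
    quiet = env < quiet_threshold * med if med > 0 else np.ones(env.size, bool)
    edges = np.flatnonzero(np.diff(quiet.astype(int)))
    starts = [0] if quiet[0] else []
    starts += [int(e) + 1 for e in edges if quiet[e + 1]]
    ends = [int(e) + 1 for e in edges if not quiet[e + 1]]
    if quiet[-1]:
        ends.append(quiet.size)
    out = []
    for s, e in zip(starts, ends):
        onset = resp.start + s / resp.rate
        offset = resp.start + e / resp.rate
        if offset - onset >= min_duration:
            out.append(BreathHoldInterval(onset, offset, source="detected"))
    return out
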