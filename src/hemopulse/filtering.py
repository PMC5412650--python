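"""Zero-phase Butterworth filtering shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import ParameterError

__all__ = ["zero_phase_filter"]


def zero_phase_filter(data: np.ndarray, rate: float, low: float | None,
                      high: float | None, order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth filter (low/high/band-pass).

    ``low`` is the lower band edge (None or 0 → low-pass only),
    ``high`` the upper edge (None or inf → high-pass only). Applied
    with :func:`scipy.signal.sosfiltfilt`, so the result is zero-phase
    and the effective attenuation is that of a filter of twice the
    order.
    """
    nyq = rate / 2.0
    lo = None if (low is None or low <= 0) else float(low)
    hi = None if (high is None or not np.isfinite(high)) else float(high)
    if lo is None and hi is None:
        return np.asarray(data, float).copy()
    if hi is not None and hi >= nyq:
        raise ParameterError(f"upper cutoff {hi} Hz must be below Nyquist ({nyq} Hz)")
    if lo is not None and lo >= nyq:
        raise ParameterError(f"lower cutoff {lo} Hz must be below Nyquist ({nyq} Hz)")
    if lo is not None and hi is not None:
        if lo >= hi:
            raise ParameterError(f"band edges must satisfy low < high, got ({lo}, {hi})")
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    elif lo is not None:
        sos = signal.butter(order, lo, btype="highpass", fs=rate, output="sos")
    else:
        sos = signal.butter(order, hi, btype="lowpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, float))
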