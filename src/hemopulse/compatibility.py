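"""Device-compatibility analysis via Welch power comparison.

To verify that an added device does not degrade a multichannel
recording, the mean Welch power of every channel is computed with and
without the device attached; a scatter of the two conditions should
fall on a line with slope ≈ 1, Pearson R² near 1, and an intercept
that is a small fraction of the mean power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import ParameterError, TimeSeries

__all__ = ["CompatReport", "welch_power", "compare_conditions"]


@dataclass
class CompatReport:
    """Linear with-vs-without fit over per-channel mean powers."""

    power_with: np.ndarray
    power_without: np.ndarray
    slope: float
    intercept: float
    pearson_r2: float
    intercept_fraction_of_mean: float
    channel_labels: list[str] = field(default_factory=list)
    welch_params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r2": self.pearson_r2,
            "intercept_fraction_of_mean": self.intercept_fraction_of_mean,
            "n_channels": int(self.power_with.size),
            "welch_params": dict(self.welch_params),
            "channels": [
                {"label": lab, "power_with": float(a), "power_without": float(b)}
                for lab, a, b in zip(
                    self.channel_labels or [str(i) for i in range(self.power_with.size)],
                    self.power_with, self.power_without)
            ],
        }


def welch_power(ts: TimeSeries, segment_length: float = 10.0, overlap: float = 0.5,
                band: tuple[float, float] | None = None,
                statistic: str = "mean") -> float:
    """Welch PSD (Hann window) reduced to one number per channel.

    ``statistic='mean'`` returns the mean PSD over ``band`` (or the
    full spectrum), in units²/Hz; ``statistic='integral'`` integrates
    the PSD over the band, giving band power in units² (Parseval:
    the full-band integral approximates the signal variance).
    """
    if ts.duration < segment_length:
        raise ParameterError(
            f"signal ({ts.duration:.3g} s) shorter than segment length "
            f"({segment_length:.3g} s)")
    if not (0 <= overlap < 1):
        raise ParameterError("overlap must be in [0, 1)")
    nperseg = int(round(segment_length * ts.rate))
    f, pxx = sps.welch(ts.data, fs=ts.rate, window="hann", nperseg=nperseg,
                       noverlap=int(round(overlap * nperseg)), detrend=False)
    if band is not None:
        lo, hi = band
        sel = (f >= lo) & (f <= hi)
        if not sel.any():
            raise ParameterError(f"band {band} contains no spectral bins")
        f, pxx = f[sel], pxx[sel]
    if statistic == "mean":
        return float(pxx.mean())
    if statistic == "integral":
        return float(np.trapezoid(pxx, f))
    raise ParameterError(f"unknown statistic {statistic!r}")


def compare_conditions(power_with: np.ndarray, power_without: np.ndarray,
                       channel_labels: list[str] | None = None,
                       welch_params: dict | None = None) -> CompatReport:
    """OLS line of the without-device powers against the with-device
    powers (with-device on the x axis), plus Pearson R² and the
    intercept expressed as a fraction of the mean with-device power."""
    pw = np.asarray(power_with, float)
    po = np.asarray(power_without, float)
    if pw.shape != po.shape or pw.ndim != 1:
        raise ParameterError("condition power vectors must be 1-D and equally long")
    if pw.size < 2:
        raise ParameterError("need at least two channels for a linear fit")
    fit = stats.linregress(pw, po)
    return CompatReport(
        power_with=pw, power_without=po,
        slope=float(fit.slope), intercept=float(fit.intercept),
        pearson_r2=float(fit.rvalue ** 2),
        intercept_fraction_of_mean=float(fit.intercept / pw.mean()),
        channel_labels=list(channel_labels or []),
        welch_params=dict(welch_params or {}),
    )
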