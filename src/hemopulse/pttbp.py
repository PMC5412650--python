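"""Per-beat pulse transit time, heart rate and blood-pressure estimation.

PTT is the delay between a proximal cardiac timing event (chest
accelerometer pulse, or the cardiac artifact on a MEG channel) and the
arrival of the pressure wave at the neck. Because pulse wave velocity
rises with arterial pressure, PTT falls when BP rises; the calibrated
map used here is the monotone power-law family

    BP(PTT) = A · PTT^(−alpha) + B,     A > 0, alpha > 0,

fit per subject against a reference cuff/volume-clamp series. Without
calibration the estimate is *relative*: a z-scored, sign-flipped PTT
series that tracks BP oscillations but carries no mmHg claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import CalibrationError, EventSeries, PairingError, ParameterError, TimeSeries
from .peaks import PeakDetectionParams, detect_peaks_guided, detect_reference_peaks, \
    qc_beat_series

__all__ = ["PTTSeries", "BPSeries", "HRSeries", "CalibrationModel",
           "compute_ptt", "compute_hr", "fit_calibration", "estimate_bp",
           "meg_ptt_bp", "ptt_bp_pipeline", "match_beat_series", "qc_ptt"]


@dataclass
class PTTSeries:
    """Per-beat transit times anchored to the proximal beat times."""

    beat_times: EventSeries      # matched proximal beats
    ptt: np.ndarray              # s, same length
    n_unmatched: int = 0
    flagged: np.ndarray | None = None  # ambiguous matches

    def __post_init__(self) -> None:
        self.ptt = np.asarray(self.ptt, float)
        if self.ptt.size != self.beat_times.n:
            raise ParameterError("ptt and beat_times must be index-aligned")
        if self.flagged is None:
            self.flagged = np.zeros(self.ptt.size, dtype=bool)

    @property
    def n(self) -> int:
        return self.ptt.size


@dataclass
class HRSeries:
    """Beat-to-beat heart rate at beat-interval midpoints."""

    times: np.ndarray   # s
    bpm: np.ndarray

    @property
    def n(self) -> int:
        return self.bpm.size


@dataclass
class BPSeries:
    """Per-beat blood-pressure estimates.

    ``mode='absolute'`` carries mmHg from a fitted calibration;
    ``mode='relative'`` is a unitless oscillation series (calibration
    omitted), sign-matched so that the value rises when PTT falls.
    """

    beat_times: EventSeries
    bp: np.ndarray
    mode: str = "absolute"

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, float)
        if self.bp.size != self.beat_times.n:
            raise ParameterError("bp and beat_times must be index-aligned")
        if self.mode not in ("absolute", "relative"):
            raise ParameterError(f"unknown BP mode {self.mode!r}")
        if not np.all(np.isfinite(self.bp)):
            raise ParameterError("BP estimates must be finite")

    @property
    def units(self) -> str:
        return "mmHg" if self.mode == "absolute" else "a.u."


@dataclass
class CalibrationModel:
    """BP = A·PTT^(−alpha) + B on ``valid_ptt_range``."""

    A: float
    alpha: float = 1.0
    B: float = 0.0
    valid_ptt_range: tuple[float, float] = (0.02, 0.5)

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.alpha > 0):
            raise CalibrationError(
                f"model must be strictly decreasing: need A > 0, alpha > 0 "
                f"(got A={self.A:.4g}, alpha={self.alpha:.4g})")
        lo, hi = self.valid_ptt_range
        if not (0 < lo < hi):
            raise CalibrationError(f"invalid ptt range {self.valid_ptt_range}")

    def predict(self, ptt: np.ndarray) -> np.ndarray:
        return self.A * np.asarray(ptt, float) ** (-self.alpha) + self.B

    def inverse(self, bp: np.ndarray) -> np.ndarray:
        """PTT producing the given BP (defined for bp > B)."""
        return (self.A / (np.asarray(bp, float) - self.B)) ** (1.0 / self.alpha)


def compute_ptt(proximal: EventSeries, distal: EventSeries,
                lag_window: tuple[float, float] = (0.02, 0.4)) -> PTTSeries:
    """Match each proximal beat to the distal arrival in its lag window.

    Matching is greedy in time with each distal event used at most
    once. A window holding several candidates takes the one nearest
    the window start and flags the beat; a window holding none drops
    the beat. More than 50 % unmatched beats raises
    :class:`PairingError` (wrong channels or window).
    """
    lo, hi = lag_window
    if not (0 <= lo < hi):
        raise ParameterError(f"invalid lag window {lag_window}")
    matched_t, ptts, flags = [], [], []
    j0 = 0
    dt = distal.times
    for tp in proximal.times:
        while j0 < dt.size and dt[j0] < tp + lo:
            j0 += 1
        j1 = j0
        while j1 < dt.size and dt[j1] <= tp + hi:
            j1 += 1
        if j1 == j0:
            continue
        matched_t.append(tp)
        ptts.append(dt[j0] - tp)
        flags.append(j1 - j0 > 1)
        j0 += 1  # consume the matched distal event
    n_unmatched = proximal.n - len(matched_t)
    if proximal.n and n_unmatched > 0.5 * proximal.n:
        raise PairingError(
            f"{n_unmatched}/{proximal.n} proximal beats unmatched in window "
            f"{lag_window}; check channel pairing")
    return PTTSeries(beat_times=EventSeries(np.asarray(matched_t), label=proximal.label),
                     ptt=np.asarray(ptts), n_unmatched=n_unmatched,
                     flagged=np.asarray(flags, bool))


def qc_ptt(series: PTTSeries, bounds: tuple[float, float] = (0.02, 0.5),
           mad_k: float = 5.0) -> tuple[PTTSeries, int]:
    """Drop transit times outside physiological bounds or median ± k·MAD."""
    p = series.ptt
    keep = (p > bounds[0]) & (p < bounds[1])
    if keep.sum() >= 3:
        med = np.median(p[keep])
        mad = np.median(np.abs(p[keep] - med))
        keep &= np.abs(p - med) <= mad_k * max(mad, 1e-4)
    out = PTTSeries(beat_times=EventSeries(series.beat_times.times[keep],
                                           label=series.beat_times.label),
                    ptt=p[keep], n_unmatched=series.n_unmatched,
                    flagged=series.flagged[keep])
    return out, int((~keep).sum())


def compute_hr(beats: EventSeries) -> HRSeries:
    """HR_i = 60 / (t_{i+1} − t_i), placed at the interval midpoint."""
    if beats.n < 2:
        raise ParameterError("need at least two beats for a heart rate")
    iv = beats.intervals()
    return HRSeries(times=beats.times[:-1] + iv / 2, bpm=60.0 / iv)


def fit_calibration(ptt: PTTSeries | np.ndarray, reference_bp: np.ndarray,
                    alpha: float = 1.0, fit_alpha: bool = False,
                    A: float | None = None) -> CalibrationModel:
    """Least-squares fit of the PTT→BP map against a reference series.

    With ``fit_alpha=False`` (default) the problem is linear in
    (A, B) at fixed ``alpha``; with ``fit_alpha=True`` all three
    parameters are fit (needs ≥3 distinct pairs). Supplying ``A``
    fixes it and solves B alone, which permits single-point
    recalibration. The fitted curve must be strictly decreasing over
    the data range (A > 0), otherwise :class:`CalibrationError`.
    """
    p = np.asarray(ptt.ptt if isinstance(ptt, PTTSeries) else ptt, float)
    bp = np.asarray(reference_bp, float)
    if p.size != bp.size:
        raise ParameterError("ptt and reference_bp lengths differ")
    if np.unique(p).size < (3 if fit_alpha else (1 if A is not None else 2)):
        raise CalibrationError("too few distinct (ptt, bp) pairs for the fit")
    if np.any(p <= 0):
        raise CalibrationError("transit times must be positive")
    rng = (float(p.min()), float(p.max()))
    if rng[0] == rng[1]:  # single-point calibration: pad the valid range
        rng = (0.8 * rng[0], 1.25 * rng[1])
    if A is not None:
        if fit_alpha:
            raise ParameterError("cannot fix A and fit alpha simultaneously")
        B = float(np.mean(bp - A * p ** (-alpha)))
        return CalibrationModel(A=A, alpha=alpha, B=B, valid_ptt_range=rng)
    x = p ** (-alpha)
    design = np.column_stack([x, np.ones_like(x)])
    (A0, B0), *_ = np.linalg.lstsq(design, bp, rcond=None)
    if A0 <= 0:
        raise CalibrationError(
            f"fitted map not decreasing (A = {A0:.4g} ≤ 0): BP does not fall with "
            "rising PTT in these data")
    if not fit_alpha:
        return CalibrationModel(A=float(A0), alpha=alpha, B=float(B0), valid_ptt_range=rng)
    popt, _ = curve_fit(lambda q, a, al, b: a * q ** (-al) + b, p, bp,
                        p0=[A0, alpha, B0], maxfev=20000)
    if popt[0] <= 0 or popt[1] <= 0:
        raise CalibrationError("three-parameter fit is not strictly decreasing")
    return CalibrationModel(A=float(popt[0]), alpha=float(popt[1]), B=float(popt[2]),
                            valid_ptt_range=rng)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    w = min(max(int(w), 1), x.size)
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def estimate_bp(ptt: PTTSeries, model: CalibrationModel | None = None,
                smooth_beats: int | None = None) -> BPSeries:
    """Per-beat BP from transit times.

    With a calibration model the absolute map BP(PTT) is applied; without
    one the output is the z-scored, sign-flipped PTT (relative mode:
    rises when PTT falls). ``smooth_beats`` applies a centred moving
    average over that many beats.
    """
    if model is not None:
        bp = model.predict(ptt.ptt)
        mode = "absolute"
    else:
        sd = ptt.ptt.std()
        bp = -(ptt.ptt - ptt.ptt.mean()) / (sd if sd > 0 else 1.0)
        mode = "relative"
    if smooth_beats:
        bp = _moving_average(bp, smooth_beats)
    return BPSeries(beat_times=ptt.beat_times, bp=bp, mode=mode)


def ptt_bp_pipeline(proximal_ts: TimeSeries, distal_ts: TimeSeries,
                    params_proximal: PeakDetectionParams | None = None,
                    params_distal: PeakDetectionParams | None = None,
                    lag_window: tuple[float, float] = (0.02, 0.4),
                    model: CalibrationModel | None = None,
                    smooth_beats: int | None = None):
    """Reference detection → guided detection → PTT → BP, with QC.

    Returns ``(BPSeries, PTTSeries, HRSeries, qc_dict)``.
    """
    params_proximal = params_proximal or PeakDetectionParams(
        highpass=2.0, smoothing_bandwidth=20.0)
    params_distal = params_distal or PeakDetectionParams(
        smoothing_bandwidth=20.0, lag_min=lag_window[0], lag_max=lag_window[1])
    ref = detect_reference_peaks(proximal_ts, params_proximal)
    ref, qc_report = qc_beat_series(ref)
    guided = detect_peaks_guided(distal_ts, ref, params_distal)
    ptt = compute_ptt(ref, guided.events(), lag_window)
    # Genuine transit times concentrate within tens of ms; spurious
    # pairings (e.g. noise-only proximal detections) spread their argmax
    # across the whole lag window.
    mad = float(np.median(np.abs(ptt.ptt - np.median(ptt.ptt))))
    if mad > 0.05:
        raise PairingError(
            f"transit times do not concentrate (MAD = {mad * 1000:.0f} ms): the "
            "proximal detections are unlikely to be heart beats")
    ptt, n_ptt_dropped = qc_ptt(ptt)
    hr = compute_hr(ref)
    bp = estimate_bp(ptt, model=model, smooth_beats=smooth_beats)
    qc = {"beats_detected": ref.n, "beat_qc": qc_report.as_dict(),
          "guided_missing": guided.n_missing, "ptt_unmatched": ptt.n_unmatched,
          "ptt_outliers_dropped": n_ptt_dropped, "beats_used": ptt.n}
    return bp, ptt, hr, qc


def meg_ptt_bp(meg_channel: TimeSeries, neck: TimeSeries,
               params_meg: PeakDetectionParams | None = None,
               params_neck: PeakDetectionParams | None = None,
               lag_window: tuple[float, float] = (0.02, 0.4)):
    """Relative BP oscillations with MEG-detected heart beats.

    The cardiac artifact on a single MEG channel replaces the chest
    accelerometer as the proximal timing reference; the MEG channel is
    band-limited (default 2–40 Hz) to suppress the 1/f background
    before free-running detection. The MEG artifact peaks at a fixed,
    modality-dependent offset from the chest pulse, so only relative
    BP is meaningful here; absolute mode would need a calibration
    acquired with the same proximal modality.

    Returns ``(BPSeries, PTTSeries, HRSeries, qc_dict)``.
    """
    # Cardiac artifacts are sparse (sub-percent duty cycle over the 1/f
    # background), so the adaptive threshold must reference a percentile
    # above the beats' time fraction, not the 95th used for ACM pulses.
    params_meg = params_meg or PeakDetectionParams(
        highpass=2.0, smoothing_bandwidth=40.0, threshold_percentile=99.5)
    return ptt_bp_pipeline(meg_channel, neck, params_meg, params_neck,
                           lag_window=lag_window, model=None)


def match_beat_series(times_a: np.ndarray, times_b: np.ndarray,
                      tol: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs of mutually nearest beats within ``tol`` seconds.

    Used to compare two per-beat series anchored on independently
    detected beats (e.g. chest-based vs MEG-based BP estimates).
    """
    ia, ib = [], []
    j = 0
    for i, ta in enumerate(np.asarray(times_a, float)):
        while j < len(times_b) - 1 and abs(times_b[j + 1] - ta) <= abs(times_b[j] - ta):
            j += 1
        if j < len(times_b) and abs(times_b[j] - ta) <= tol:
            ia.append(i)
            ib.append(j)
            j += 1
    return np.asarray(ia, int), np.asarray(ib, int)
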