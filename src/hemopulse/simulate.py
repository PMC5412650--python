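"""Synthetic multimodal physiology with known ground truth.

The simulator produces the latent physiological state (blood pressure,
heart rate, respiration, per-beat pulse transit time, hemoglobin
concentration changes) and renders every sensor channel the analysis
pipeline consumes:

* chest accelerometer — one pulse wavelet per heart beat plus a
  respiration component,
* neck accelerometer — pulse wavelet delayed by the true per-beat PTT,
* MEG channel — a cardiac artifact wavelet per beat over 1/f-shaped
  background noise,
* dual-wavelength NIRS intensities — forward modified Beer–Lambert
  rendering of the prescribed ΔHbO/ΔHb trajectories.

Blood pressure combines a constant baseline, a Mayer-wave sinusoid
(~0.1 Hz) and breath-hold ramps (linear rise during a hold, exponential
relaxation afterwards). True PTT is coupled to BP through the inverse
of the calibration map BP = A·PTT^(−α) + B, so higher pressure means
shorter transit time. Beat times come from integrating the
instantaneous heart rate to unit threshold (the standard inhomogeneous
point-process construction). Everything is deterministic given
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError, EventSeries, Recording, TimeSeries
from .filtering import zero_phase_filter
from .nirs import NIRSGeometry

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_ground_truth",
    "render_chest_acm",
    "render_neck_acm",
    "render_meg_channel",
    "render_nirs",
    "simulate_recording",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic session.

    Amplitude units follow the quantity they scale: mmHg for blood
    pressure, bpm for heart rate, µM for hemoglobin, arbitrary sensor
    units for accelerometer/MEG amplitudes and noise.
    """

    duration: float = 120.0          # s
    sample_rate: float = 1000.0      # Hz, all rendered channels
    seed: int = 0

    # Cardiac rhythm
    baseline_hr: float = 60.0        # bpm
    hr_variability_sd: float = 3.0   # bpm, band-limited (0.04-0.4 Hz) Gaussian
    hr_hold_dip: float = 3.0         # bpm slight decrease during a hold

    # Blood pressure
    baseline_map: float = 100.0      # mmHg
    mayer_amplitude: float = 5.0     # mmHg
    mayer_frequency: float = 0.1     # Hz
    bp_hold_ramp: float = 10.0       # mmHg reached at the end of a hold
    hold_relax_tau: float = 10.0     # s, post-hold exponential relaxation

    # PTT↔BP coupling: BP = A·PTT^(−alpha) + B
    cal_A: float = 7.2               # mmHg·s^alpha
    cal_alpha: float = 1.0
    cal_B: float = 40.0              # mmHg

    # Respiration
    respiration_rate: float = 0.25   # Hz
    respiration_amplitude: float = 1.0
    breath_hold_schedule: tuple[tuple[float, float], ...] = ()  # (onset s, duration s)
    hold_transition: float = 2.0     # s, smooth gating of respiration at hold edges

    # Accelerometer channels
    pulse_amplitude: float = 1.0
    pulse_sigma: float = 0.025       # s, Gaussian pulse wavelet width
    chest_noise_sd: float = 0.05
    neck_noise_sd: float = 0.05

    # MEG channel
    meg_artifact_amplitude: float = 1.0
    meg_artifact_sigma: float = 0.015  # s, sharper than the ACM pulse
    meg_artifact_latency: float = -0.02  # s; cardiac electrical event leads chest motion
    meg_background_sd: float = 0.1
    meg_background_exponent: float = 1.0  # 1/f^exponent spectral shaping

    # NIRS
    nirs_geometry: NIRSGeometry = field(default_factory=NIRSGeometry)
    nirs_i0: float = 1.0
    nirs_noise_sd: float = 0.001     # multiplicative
    hbo_hold_dip: float = 1.0        # µM transient decrease during hold
    hb_hold_rise: float = 0.2        # µM slight transient increase
    hemo_relax_tau: float = 10.0     # s

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ConfigError(f"duration must be > 0, got {self.duration}")
        for name in ("mayer_amplitude", "hr_variability_sd", "bp_hold_ramp",
                     "respiration_amplitude", "pulse_amplitude", "chest_noise_sd",
                     "neck_noise_sd", "meg_artifact_amplitude", "meg_background_sd",
                     "nirs_noise_sd", "hbo_hold_dip", "hb_hold_rise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        holds = sorted(self.breath_hold_schedule)
        for onset, dur in holds:
            if dur <= 0 or onset < 0 or onset + dur > self.duration:
                raise ConfigError(f"hold ({onset}, {dur}) outside [0, {self.duration}] s")
        for (o1, d1), (o2, _) in zip(holds, holds[1:]):
            if o1 + d1 > o2:
                raise ConfigError(f"overlapping holds at {o1} s and {o2} s")
        self.breath_hold_schedule = tuple(holds)

    @classmethod
    def breath_hold_protocol(cls, n_holds: int = 5, hold_duration: float = 30.0,
                             first_onset: float = 30.0, rest_duration: float = 30.0,
                             tail: float = 90.0, **kw) -> "SimulationConfig":
        """Config for the breath-hold task: ``n_holds`` holds of
        ``hold_duration`` s separated by ``rest_duration`` s of normal
        breathing, with enough tail for an 80 s post-onset epoch."""
        cycle = hold_duration + rest_duration
        schedule = tuple((first_onset + i * cycle, hold_duration) for i in range(n_holds))
        duration = kw.pop("duration", first_onset + (n_holds - 1) * cycle + tail)
        return cls(duration=duration, breath_hold_schedule=schedule, **kw)


@dataclass
class GroundTruth:
    """Latent state of a simulated session (the recovery oracle)."""

    bp: TimeSeries               # mmHg
    hr: TimeSeries               # bpm
    respiration: TimeSeries      # a.u.
    beat_times: EventSeries
    true_ptt: np.ndarray         # s, aligned with beat_times
    hbo: TimeSeries              # µM
    hb: TimeSeries               # µM
    config: SimulationConfig

    def bp_at_beats(self) -> np.ndarray:
        return np.interp(self.beat_times.times, self.bp.times, self.bp.data)

    def hr_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.hr.times, self.hr.data)


def _hold_response(t: np.ndarray, schedule, amplitude: float, tau: float) -> np.ndarray:
    """Linear 0→amplitude ramp during each hold, exp(−Δt/τ) relaxation after."""
    out = np.zeros_like(t)
    for onset, dur in schedule:
        during = (t >= onset) & (t < onset + dur)
        after = t >= onset + dur
        out[during] += amplitude * (t[during] - onset) / dur
        out[after] += amplitude * np.exp(-(t[after] - onset - dur) / tau)
    return out


def _respiration_gate(t: np.ndarray, schedule, transition: float) -> np.ndarray:
    """1 while breathing, smoothly (raised-cosine) to 0 inside holds."""
    gate = np.ones_like(t)
    w = max(transition, 1e-6)

    def step(x):  # 0 → 1 over [0, w], raised cosine
        return 0.5 * (1 - np.cos(np.pi * np.clip(x / w, 0, 1)))

    for onset, dur in schedule:
        # suppression rises across the onset and falls across the offset,
        # each transition centred on the scheduled edge
        suppression = step(t - onset + w / 2) * step(onset + dur - t + w / 2)
        gate *= 1 - suppression
    return gate


def _banded_noise(rng: np.random.Generator, n: int, rate: float,
                  low: float = 0.04, high: float = 0.4) -> np.ndarray:
    """Unit-SD band-limited Gaussian noise (HRV driver).

    The default band spans the conventional LF + HF heart-rate
    variability range (0.04–0.4 Hz), so rate fluctuations are
    oscillatory rather than drifting. Generated with padding so the
    zero-phase filter's edge transients fall outside the returned
    segment.
    """
    pad = min(int(round(3.0 / low * rate)), n)
    x = rng.standard_normal(n + 2 * pad)
    y = zero_phase_filter(x, rate, low, high, order=2)[pad:pad + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def ptt_from_bp(bp: np.ndarray, A: float, alpha: float, B: float) -> np.ndarray:
    """Invert BP = A·PTT^(−α) + B. Strictly decreasing in BP."""
    return (A / (np.asarray(bp, float) - B)) ** (1.0 / alpha)


def simulate_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Draw the latent physiology for one session.

    Determinism: identical ``cfg`` (including ``cfg.seed``) yields
    identical output arrays.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n = int(round(cfg.duration * fs))
    t = np.arange(n) / fs

    hr = np.full(n, cfg.baseline_hr)
    if cfg.hr_variability_sd > 0:
        hr = hr + cfg.hr_variability_sd * _banded_noise(rng, n, fs)
    if cfg.breath_hold_schedule and cfg.hr_hold_dip:
        hr = hr - _hold_response(t, cfg.breath_hold_schedule, cfg.hr_hold_dip,
                                 cfg.hold_relax_tau)

    phase = rng.uniform(0, 2 * np.pi) if cfg.mayer_amplitude > 0 else 0.0
    bp = (cfg.baseline_map
          + cfg.mayer_amplitude * np.sin(2 * np.pi * cfg.mayer_frequency * t + phase)
          + _hold_response(t, cfg.breath_hold_schedule, cfg.bp_hold_ramp, cfg.hold_relax_tau))

    # Beats: integrate instantaneous rate (Hz) to unit threshold.
    cum = np.cumsum(hr / 60.0) / fs
    k = np.arange(1, int(np.floor(cum[-1])) + 1)
    beat_times = np.interp(k, cum, t + 1.0 / fs)
    beat_times = beat_times[(beat_times > 0) & (beat_times < cfg.duration)]
    beats = EventSeries(beat_times, label="true_beats")

    bp_at_beats = np.interp(beat_times, t, bp)
    true_ptt = ptt_from_bp(bp_at_beats, cfg.cal_A, cfg.cal_alpha, cfg.cal_B)

    resp = (cfg.respiration_amplitude
            * np.sin(2 * np.pi * cfg.respiration_rate * t)
            * _respiration_gate(t, cfg.breath_hold_schedule, cfg.hold_transition))

    hbo = -_hold_response(t, cfg.breath_hold_schedule, cfg.hbo_hold_dip, cfg.hemo_relax_tau)
    hb = _hold_response(t, cfg.breath_hold_schedule, cfg.hb_hold_rise, cfg.hemo_relax_tau)

    mk = dict(rate=fs, start=0.0)
    return GroundTruth(
        bp=TimeSeries(bp, label="bp", units="mmHg", **mk),
        hr=TimeSeries(hr, label="hr", units="bpm", **mk),
        respiration=TimeSeries(resp, label="respiration", units="a.u.", **mk),
        beat_times=beats,
        true_ptt=true_ptt,
        hbo=TimeSeries(hbo, label="hbo", units="uM", **mk),
        hb=TimeSeries(hb, label="hb", units="uM", **mk),
        config=cfg,
    )


def _wavelet_train(n: int, fs: float, centers: np.ndarray, amplitude: float,
                   sigma: float) -> np.ndarray:
    """Sum of Gaussian wavelets; each evaluated on a ±6σ support only."""
    out = np.zeros(n)
    half = int(np.ceil(6 * sigma * fs))
    for c in centers:
        ic = int(round(c * fs))
        i0, i1 = max(ic - half, 0), min(ic + half + 1, n)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) / fs - c
        out[i0:i1] += amplitude * np.exp(-0.5 * (tt / sigma) ** 2)
    return out


def render_chest_acm(gt: GroundTruth, cfg: SimulationConfig | None = None) -> TimeSeries:
    """Chest accelerometer: pulse per beat + respiration + white noise."""
    cfg = cfg or gt.config
    fs = cfg.sample_rate
    n = gt.bp.n
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    sig = _wavelet_train(n, fs, gt.beat_times.times, cfg.pulse_amplitude, cfg.pulse_sigma)
    sig += gt.respiration.data
    if cfg.chest_noise_sd > 0:
        sig = sig + cfg.chest_noise_sd * rng.standard_normal(n)
    return TimeSeries(sig, rate=fs, label="chest", units="a.u.")


def render_neck_acm(gt: GroundTruth, cfg: SimulationConfig | None = None) -> TimeSeries:
    """Neck accelerometer: pulse per beat delayed by the true PTT."""
    cfg = cfg or gt.config
    fs = cfg.sample_rate
    n = gt.bp.n
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    centers = gt.beat_times.times + gt.true_ptt
    sig = _wavelet_train(n, fs, centers, cfg.pulse_amplitude, cfg.pulse_sigma)
    if cfg.neck_noise_sd > 0:
        sig = sig + cfg.neck_noise_sd * rng.standard_normal(n)
    return TimeSeries(sig, rate=fs, label="neck", units="a.u.")


def one_over_f_noise(rng: np.random.Generator, n: int, rate: float,
                     exponent: float = 1.0) -> np.ndarray:
    """Unit-SD noise with a 1/f^exponent power spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    fourier = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC divergence
    y = np.fft.irfft(fourier * shape, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def render_meg_channel(gt: GroundTruth, cfg: SimulationConfig | None = None) -> TimeSeries:
    """One MEG channel: cardiac artifact per beat over 1/f background."""
    cfg = cfg or gt.config
    fs = cfg.sample_rate
    n = gt.bp.n
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    centers = gt.beat_times.times + cfg.meg_artifact_latency
    centers = centers[(centers > 0) & (centers < n / fs)]
    sig = _wavelet_train(n, fs, centers, cfg.meg_artifact_amplitude, cfg.meg_artifact_sigma)
    if cfg.meg_background_sd > 0:
        sig = sig + cfg.meg_background_sd * one_over_f_noise(
            rng, n, fs, cfg.meg_background_exponent)
    return TimeSeries(sig, rate=fs, label="meg", units="a.u.")


def render_nirs(gt: GroundTruth, cfg: SimulationConfig | None = None
                ) -> tuple[TimeSeries, TimeSeries]:
    """Forward MBLL rendering of the two detector intensities.

    ΔOD(λ, t) = d · DPF(λ) · [ε_HbO(λ)·ΔHbO(t) + ε_Hb(λ)·ΔHb(t)] and
    I(λ, t) = I0 · 10^(−ΔOD), with optional multiplicative noise.
    """
    cfg = cfg or gt.config
    geom = cfg.nirs_geometry
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    conc = np.vstack([gt.hbo.data, gt.hb.data])  # (2, n)
    out = []
    for i, lam in enumerate(geom.wavelengths):
        eps = geom.extinction[i]  # (ε_HbO, ε_Hb) at this wavelength
        delta_od = geom.source_detector_distance * geom.dpf[i] * (eps @ conc)
        intensity = cfg.nirs_i0 * 10.0 ** (-delta_od)
        if cfg.nirs_noise_sd > 0:
            intensity = intensity * (1 + cfg.nirs_noise_sd * rng.standard_normal(conc.shape[1]))
        out.append(TimeSeries(intensity, rate=cfg.sample_rate,
                              label=f"nirs_{int(round(lam))}", units="a.u."))
    return out[0], out[1]


def simulate_recording(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Render the full multichannel session the pipeline consumes."""
    gt = simulate_ground_truth(cfg)
    rec = Recording(metadata={"simulated": True, "seed": cfg.seed,
                              "duration": cfg.duration})
    for ts in (render_chest_acm(gt, cfg), render_neck_acm(gt, cfg),
               render_meg_channel(gt, cfg)):
        rec.add_channel(ts)
    i660, i850 = render_nirs(gt, cfg)
    rec.add_channel(i660)
    rec.add_channel(i850)
    if cfg.breath_hold_schedule:
        rec.add_markers(EventSeries(np.array([o for o, _ in cfg.breath_hold_schedule]),
                                    label="hold_onset"))
    return rec, gt


def ground_truth_recording(gt: GroundTruth) -> Recording:
    """Package the latent state as a recording (for the CLI sidecar)."""
    rec = Recording(metadata={"ground_truth": True, "seed": gt.config.seed})
    for ts in (gt.bp, gt.hr, gt.respiration, gt.hbo, gt.hb):
        rec.add_channel(ts)
    rec.add_markers(EventSeries(gt.beat_times.times, label="true_beats"))
    return rec
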