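# Methods

This note documents the models, defaults and numerical choices behind
hemopulse, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Signal model and containers

All channels are uniformly sampled `TimeSeries` (rate in Hz, start time
in seconds, t = 0 at recording start); beats and stimulus markers are
strictly increasing `EventSeries` in recording time, never sample
indices. A `Recording` groups channels of possibly different rates over
a common span. On disk a recording is a plain CSV (one column per
channel, shorter columns padded with empty cells), a YAML sidecar with
per-channel rate/units/start, and an optional two-column marker TSV.
Floats are written with 12 significant digits, so read∘write reproduces
samples to better than 1e-9 relative error. The reader rejects files
violating container invariants (duplicate labels, non-numeric cells with
the offending line number, inconsistent spans) and never silently
repairs. EDF can be read when `mne` is installed; EDF writing is not
supported.

## Beat detection

Detection is two-stage, mirroring reference-guided maximum-in-interval
search:

1. **Free-running reference detection** on the channel with the clearest
   pulse. The signal is optionally band-limited (chest default: 2 Hz
   high-pass to remove respiration, 20 Hz low-pass to suppress wideband
   noise without biasing the symmetric pulse peak — both zero-phase, so
   peak positions are preserved), baseline-subtracted by a rolling
   median, and local maxima are kept when they exceed an adaptive
   threshold — a configurable fraction (default 0.5) of a rolling
   percentile (default 95th over 10 s) — separated by a refractory
   interval (default 0.3 s). Baseline subtraction plus a
   percentile-relative threshold make detection invariant to positive
   affine rescaling of the input.

   For MEG cardiac artifacts the same rule is used at the **99.5th**
   percentile: the artifact occupies well under 1 % of samples over a
   1/f background, so the 95th percentile of the signal distribution
   sits inside the noise rather than on the pulses. The percentile is
   an exposed parameter; `meg_ptt_bp` sets this default together with a
   2–40 Hz pass band.

2. **Guided detection** on every other channel: for each reference beat
   the per-polarity argmax inside `[ref + 20 ms, ref + 400 ms]`
   (physiological chest→neck transit bounds; configurable) is taken, at
   sample resolution, earliest sample winning ties so the result is
   deterministic and exactly equal to a brute-force per-window argmax.
   Windows falling outside the recording mark the beat missing rather
   than fabricating one.

**Beat QC** replaces manual visual checking. Intervals below 0.3 s or
below `median − k·MAD` (k = 5) mark a spurious detection; of the two
events forming the short interval, the one whose removal best restores
the local rhythm (merged interval closest to the median) is dropped,
iteratively. The MAD scale is floored at 5 % of the median interval:
genuine slow rhythm wander keeps the raw interval MAD small, and without
the floor normal heart-rate variability would be flagged. Intervals
above 1.7× the median (or 2 s) are flagged as missed-beat gaps but never
filled in.

## PTT, HR and blood pressure

Per-beat PTT matches each proximal beat to the unique distal event in
its lag window, greedily in time with each distal event consumed at most
once; ambiguous windows take the candidate nearest the window start and
flag the beat. More than 50 % unmatched beats raises a pairing error
(wrong channels or window). A second pairing gate checks dispersion:
genuine transit times concentrate within tens of milliseconds, so a
per-beat PTT MAD above 50 ms (spurious detections spread their argmax
over the whole window) also raises a pairing error. Afterwards, PTT
values outside (20, 500) ms or beyond median ± 5·MAD are dropped.

Heart rate is `HR_i = 60/(t_{i+1} − t_i)` placed at interval midpoints.

The PTT→BP map is `BP = A·PTT^(−α) + B` with α > 0 and A > 0 (strictly
decreasing, hence invertible). Calibration fits (A, B) by linear least
squares at fixed α (default 1), optionally all three parameters by
Levenberg–Marquardt seeded from the linear fit; a non-decreasing fit
(A ≤ 0) is an error, not a warning, because it contradicts the
pressure–velocity physiology. Supplying A fixes it and solves B alone
(single-point recalibration). Without calibration the estimate is
*relative*: z-scored, sign-flipped PTT, rising when PTT falls. The MEG
artifact peaks at a fixed, modality-dependent offset from the chest
pulse, so MEG-proximal estimates are only meaningful in relative mode
(or with a calibration acquired against the same proximal modality).

## Respiration and breath holds

Respiration is a zero-phase 4th-order Butterworth low-pass (default
cutoff 0.5 Hz) of an ACM channel; forward–backward application doubles
the effective order and removes phase distortion. Hold detection
computes a centred rolling SD envelope (5 s window) and marks maximal
runs where the envelope stays below a fraction (default 0.25) of the
recording's median envelope for at least `min_duration`. The threshold
is relative, so a recording that contains no breathing anywhere has no
amplitude scale; only an exactly zero envelope is classified as one
spanning hold. Task markers are the preferred hold source; envelope
detection is a convenience for unmarked data, and its onsets are blurred
by roughly half the envelope window (≈ 2 s).

## NIRS / MBLL

ΔOD(λ, t) = −log10(I/Ī_baseline) with the baseline the mean intensity
over a window (default the first 30 s). Concentration changes solve the
2×2 system ΔOD(λ) = d·DPF(λ)·[ε_HbO(λ)·ΔHbO + ε_Hb(λ)·ΔHb] per sample;
a condition number above 1e6 on the pathlength-scaled extinction matrix
is a geometry error. Defaults: wavelengths 660/850 nm, d = 3 cm,
DPF = 6.0 at both wavelengths (configurable; DPF is instrument- and
tissue-dependent and no universal value exists), extinction coefficients
from Prahl's compiled molar-extinction tabulation converted to
1/(µM·cm) — 660 nm: ε_HbO = 3.1964e-4, ε_Hb = 3.2266e-3; 850 nm:
ε_HbO = 1.0580e-3, ε_Hb = 6.9132e-4. No partial-volume correction is
applied (plain MBLL); an optional scalar is exposed. ΔHbT = ΔHbO + ΔHb
by definition.

## Epoching and averaging

Epochs span −5 s to +80 s around each hold onset; windows extending past
the recording are dropped with a warning. Irregular per-beat series are
linearly interpolated onto a uniform 4 Hz grid before epoching (the
underlying physiology of interest is below 0.5 Hz; 4 Hz keeps files
small without aliasing the beat-domain series, which are first
anti-alias filtered when decimated from a faster grid). Baseline
correction subtracts each epoch's own whole-interval mean and is
idempotent. Averages report the pointwise mean and *sample* SD (n−1
denominator; SD ≡ 0 for a single epoch). Epoch inclusion masks are
exposed rather than any automated rejection rule.

## Device-compatibility analysis

Welch PSD with a Hann window, 10 s segments, 50 % overlap (all
configurable and echoed into the report). One number per channel: the
mean PSD over a band (units²/Hz) or the band-integrated power (units²;
the full-band integral approximates the variance, which is the Parseval
cross-check used in the tests). The comparison fits an OLS line of the
without-device powers against the with-device powers (with-device on the
x axis, so a device-induced power loss appears as a positive intercept),
and reports slope, intercept, Pearson R² and the intercept as a fraction
of the mean with-device power.

## The synthetic-data generator

The simulator is first-class, tested code; its defaults define the study
conditions every quantitative claim in the test suite is measured under.

Latent state, 1 kHz default sampling:

- **BP(t)** = 100 mmHg baseline + a 5 mmHg, 0.1 Hz Mayer-wave sinusoid
  (random phase) + breath-hold ramps: linear rise to 10 mmHg at the end
  of each hold, exponential relaxation (τ = 10 s) afterwards.
- **HR(t)** = 60 bpm + band-limited Gaussian variability (SD 3 bpm,
  band 0.04–0.4 Hz — the conventional LF+HF HRV range, so fluctuations
  oscillate rather than drift) − a hold-locked dip of 3 bpm with the
  same ramp/relax shape. Beats integrate HR(t)/60 to unit threshold
  (inhomogeneous point-process construction), so the degenerate
  constant-rate case yields exactly periodic beats.
- **True PTT** per beat inverts the calibration map at the beat-time BP
  with A = 7.2 mmHg·s, α = 1, B = 40 mmHg, chosen so that 100 mmHg maps
  to 120 ms and the physiological 50–300 ms band covers BP 64–184 mmHg.
  Higher BP ⇒ strictly shorter PTT, by construction.
- **Respiration**: 0.25 Hz sinusoid, smoothly gated to zero inside
  holds (raised-cosine transitions of 2 s centred on the hold edges).
- **ΔHbO/ΔHb**: hold-locked transients, −1 µM dip for HbO and +0.2 µM
  rise for Hb (ramp/relax shape, τ = 10 s). Published figures of this
  protocol are qualitative, so these are order-of-magnitude defaults
  exposed in the config.

Rendered channels:

- **Chest ACM**: one Gaussian pulse wavelet (σ = 25 ms, amplitude 1) per
  beat + the respiration waveform + white noise (SD 0.05).
- **Neck ACM**: the same wavelet delayed by the true per-beat PTT +
  white noise (SD 0.05).
- **MEG channel**: a sharper cardiac-artifact wavelet (σ = 15 ms,
  amplitude 1) per beat at a fixed −20 ms latency (the electrical event
  leads chest-wall motion), over 1/f-shaped background noise (SD 0.1,
  spectral shaping of white noise, exponent 1) — a clearly visible
  artifact, as in recordings where MEG heartbeat peaks are evident.
- **NIRS intensities**: forward MBLL, I = I0·10^(−ΔOD), with optional
  multiplicative noise (SD 0.1 %).

Everything is deterministic given (config, seed); per-channel noise
streams are derived from independent seed sequences.

The breath-hold task preset is 5 holds of 30 s separated by 30 s of
normal breathing, first onset at 30 s, with a 90 s tail so the last
−5…80 s epoch fits (360 s total).

**What the simulator does not emulate** — and hence what passing tests
do *not* show about real data: motion artifacts and sensor detachment;
beat-morphology variability and amplitude modulation of the pulse
wavelet; arrhythmia/ectopic beats; respiratory sinus arrhythmia coupling
between the respiration and HR processes; pulse-wave shape change with
pressure (only timing shifts are modelled); real MEG neural background
(only 1/f noise); NIRS superficial/systemic contamination and
partial-volume effects; inter-device clock drift (a shared clock is
assumed; resynchronization is left to the user).

## Problem sizes

The validation suite measures recovery on 120 s sessions (five seeds)
for the correlation properties and one 360 s task session for the
breath-hold protocol; these lengths give ≥ 115 beats and 5 epochs per
session, enough that the reported correlations are stable to the second
decimal while the whole suite runs in seconds.

## Known limitations

- Absolute BP accuracy is out of scope: no cuff-standard validation is
  claimed, and relative mode deliberately carries no mmHg units.
- Foot-of-wave PTT timing is not implemented (peak timing only).
- The guided detector assumes one pulse per reference window; fast
  arrhythmias violate this.
- Hold detection needs breathing before/after the hold to establish an
  envelope scale.
- The compatibility report supports channel-group labels but no
  per-sensor-type physical modelling.
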