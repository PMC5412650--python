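"""Ground-truth generator and sensor-channel renderers."""

import numpy as np
import pytest

from hemopulse import (ConfigError, SimulationConfig, simulate_ground_truth,
                       simulate_recording, render_chest_acm, render_meg_channel,
                       render_neck_acm, render_nirs, compute_delta_od, mbll_inverse)
from hemopulse.filtering import zero_phase_filter


def test_degenerate_constant_case(quiet_cfg):
    gt = simulate_ground_truth(quiet_cfg)
    np.testing.assert_allclose(gt.beat_times.intervals(), 1.0, atol=1e-9)
    assert np.ptp(gt.bp.data) == 0.0
    np.testing.assert_allclose(gt.true_ptt, gt.true_ptt[0], atol=1e-12)


def test_ptt_strictly_decreasing_in_bp():
    cfg = SimulationConfig(duration=100.0, seed=2, mayer_amplitude=0.0,
                           breath_hold_schedule=((20.0, 30.0),))
    gt = simulate_ground_truth(cfg)
    beats = gt.beat_times.times
    in_ramp = (beats > 21) & (beats < 49)
    bp = gt.bp_at_beats()[in_ramp]
    ptt = gt.true_ptt[in_ramp]
    order = np.argsort(bp)
    assert np.all(np.diff(ptt[order]) < 0)
    # invariants on the latent state
    assert np.all((gt.true_ptt > 0.02) & (gt.true_ptt < 0.5))
    assert np.all((gt.beat_times.intervals() > 0.3) & (gt.beat_times.intervals() < 2.0))
    assert np.all((gt.bp.data > 40) & (gt.bp.data < 220))


def test_seed_changes_jitter_not_means():
    means = []
    for seed in range(20):
        gt = simulate_ground_truth(SimulationConfig(duration=60.0, seed=seed))
        means.append(gt.beat_times.intervals().mean())
    means = np.asarray(means)
    assert np.ptp(means) > 0  # seeds genuinely differ
    se = means.std(ddof=1) / np.sqrt(means.size)
    assert abs(means.mean() - 1.0) <= 3 * se + 1e-3


def test_determinism(default_session):
    cfg, rec, gt = default_session
    rec2, gt2 = simulate_recording(SimulationConfig(duration=120.0, seed=1))
    for lab in rec.channels:
        np.testing.assert_array_equal(rec.channels[lab].data, rec2.channels[lab].data)
    np.testing.assert_array_equal(gt.beat_times.times, gt2.beat_times.times)


def test_overlapping_holds_rejected():
    with pytest.raises(ConfigError, match="overlap"):
        SimulationConfig(duration=100.0, breath_hold_schedule=((10, 30), (30, 30)))
    with pytest.raises(ConfigError, match="outside"):
        SimulationConfig(duration=50.0, breath_hold_schedule=((30, 30),))


def test_chest_argmax_recovers_beats(quiet_cfg):
    gt = simulate_ground_truth(quiet_cfg)
    chest = render_chest_acm(gt, quiet_cfg)
    for b in gt.beat_times.times:
        i0, i1 = chest.index_of(b - 0.15), chest.index_of(b + 0.15)
        peak = chest.start + (i0 + np.argmax(chest.data[i0:i1 + 1])) / chest.rate
        assert abs(peak - b) <= 1.0 / chest.rate


def test_chest_respiration_component(quiet_cfg):
    import dataclasses
    cfg = dataclasses.replace(quiet_cfg, respiration_amplitude=1.0, pulse_amplitude=0.0)
    gt = simulate_ground_truth(cfg)
    chest = render_chest_acm(gt, cfg)
    low = zero_phase_filter(chest.data, chest.rate, None, 0.5)
    r = np.corrcoef(low, gt.respiration.data)[0, 1]
    assert r > 0.99


def test_all_amplitudes_zero_gives_zero_signal(quiet_cfg):
    import dataclasses
    cfg = dataclasses.replace(quiet_cfg, pulse_amplitude=0.0)
    gt = simulate_ground_truth(cfg)
    assert np.all(render_chest_acm(gt, cfg).data == 0)
    assert np.all(render_neck_acm(gt, cfg).data == 0)


def test_neck_delay_equals_true_ptt(quiet_cfg):
    gt = simulate_ground_truth(quiet_cfg)
    chest = render_chest_acm(gt, quiet_cfg)
    neck = render_neck_acm(gt, quiet_cfg)
    for b, p in zip(gt.beat_times.times, gt.true_ptt):
        ic = chest.index_of(b - 0.15), chest.index_of(b + 0.15)
        inn = neck.index_of(b + p - 0.15), neck.index_of(b + p + 0.15)
        tc = (ic[0] + np.argmax(chest.data[ic[0]:ic[1] + 1])) / chest.rate
        tn = (inn[0] + np.argmax(neck.data[inn[0]:inn[1] + 1])) / neck.rate
        assert abs((tn - tc) - p) <= 1.0 / chest.rate + 1e-12


def test_neck_tracks_ptt_during_bp_ramp():
    cfg = SimulationConfig(duration=90.0, seed=4, hr_variability_sd=0.0,
                           mayer_amplitude=0.0, chest_noise_sd=0.0, neck_noise_sd=0.0,
                           respiration_amplitude=0.0, breath_hold_schedule=((20.0, 30.0),))
    gt = simulate_ground_truth(cfg)
    chest = render_chest_acm(gt, cfg)
    neck = render_neck_acm(gt, cfg)
    errs = []
    for b, p in zip(gt.beat_times.times, gt.true_ptt):
        ic = chest.index_of(b - 0.15), chest.index_of(b + 0.15)
        inn = neck.index_of(b + p - 0.15), neck.index_of(b + p + 0.15)
        tc = (ic[0] + np.argmax(chest.data[ic[0]:ic[1] + 1])) / chest.rate
        tn = (inn[0] + np.argmax(neck.data[inn[0]:inn[1] + 1])) / neck.rate
        errs.append(abs((tn - tc) - p))
    assert max(errs) <= 2.0 / chest.rate + 1e-12


def test_meg_clean_background_peaks_at_beats(quiet_cfg):
    gt = simulate_ground_truth(quiet_cfg)
    meg = render_meg_channel(gt, quiet_cfg)
    lat = quiet_cfg.meg_artifact_latency
    for b in gt.beat_times.times:
        c = b + lat
        if c < 0.1 or c > meg.duration - 0.1:
            continue
        i0, i1 = meg.index_of(c - 0.1), meg.index_of(c + 0.1)
        peak = (i0 + np.argmax(meg.data[i0:i1 + 1])) / meg.rate
        assert abs(peak - c) <= 1.0 / meg.rate


def test_meg_default_snr_beat_recovery():
    """≥95% of true beats recovered from a 60 s default-SNR MEG channel."""
    from hemopulse import PeakDetectionParams, detect_reference_peaks
    cfg = SimulationConfig(duration=60.0, seed=7)
    gt = simulate_ground_truth(cfg)
    meg = render_meg_channel(gt, cfg)
    params = PeakDetectionParams(highpass=2.0, smoothing_bandwidth=40.0,
                                 threshold_percentile=99.5)
    det = detect_reference_peaks(meg, params).times - cfg.meg_artifact_latency
    hits = sum(np.min(np.abs(det - b)) <= 0.02 for b in gt.beat_times.times)
    assert hits / gt.beat_times.n >= 0.95


def test_meg_no_artifact_detections_at_chance():
    """Without a cardiac artifact, detections are not beat-locked."""
    from hemopulse import PeakDetectionParams, detect_reference_peaks
    cfg = SimulationConfig(duration=60.0, seed=8, meg_artifact_amplitude=0.0)
    gt = simulate_ground_truth(cfg)
    meg = render_meg_channel(gt, cfg)
    params = PeakDetectionParams(highpass=2.0, smoothing_bandwidth=40.0)
    det = detect_reference_peaks(meg, params).times - cfg.meg_artifact_latency
    if det.size == 0:
        return
    hits = sum(np.min(np.abs(det - b)) <= 0.02 for b in gt.beat_times.times)
    # chance level: ±20 ms windows at ~1 Hz beats cover ~4% of the time axis
    assert hits / gt.beat_times.n < 0.2


def test_nirs_forward_inverse_roundtrip(protocol_session):
    import dataclasses
    cfg = dataclasses.replace(protocol_session[0], nirs_noise_sd=0.0)
    gt = simulate_ground_truth(cfg)
    i660, i850 = render_nirs(gt, cfg)
    hemo = mbll_inverse(compute_delta_od(i660, (0, 30)),
                        compute_delta_od(i850, (0, 30)), cfg.nirs_geometry)
    assert np.abs(hemo.delta_hbo.data - gt.hbo.data).max() <= 1e-6
    assert np.abs(hemo.delta_hb.data - gt.hb.data).max() <= 1e-6


def test_nirs_constant_concentrations_give_constant_intensity(quiet_cfg):
    gt = simulate_ground_truth(quiet_cfg)  # no holds → ΔHbO = ΔHb = 0
    i660, i850 = render_nirs(gt, quiet_cfg)
    np.testing.assert_allclose(i660.data, quiet_cfg.nirs_i0, rtol=1e-12)
    np.testing.assert_allclose(i850.data, quiet_cfg.nirs_i0, rtol=1e-12)


def test_nirs_noise_recovery_unbiased_and_averaging_shrinks_error():
    """Monte-Carlo: MBLL inversion of noisy intensities is unbiased and the
    error of the across-run mean shrinks with the number of runs."""
    base = SimulationConfig(duration=40.0, seed=0, nirs_noise_sd=0.01,
                            breath_hold_schedule=((10.0, 20.0),))
    recov = []
    for seed in range(12):
        import dataclasses
        cfg = dataclasses.replace(base, seed=seed)
        gt = simulate_ground_truth(cfg)
        i660, i850 = render_nirs(gt, cfg)
        hemo = mbll_inverse(compute_delta_od(i660, (0, 5)),
                            compute_delta_od(i850, (0, 5)), cfg.nirs_geometry)
        recov.append(hemo.delta_hbo.data - gt.hbo.data)
    recov = np.asarray(recov)
    per_run_rms = np.sqrt((recov ** 2).mean(axis=1)).mean()
    mean_rms = np.sqrt((recov.mean(axis=0) ** 2).mean())
    assert abs(recov.mean()) < 0.05          # unbiased
    assert mean_rms < per_run_rms / 2        # averaging helps ~1/sqrt(12)
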