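"""PTT matching, heart rate, calibration fitting and BP estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemopulse import (CalibrationError, CalibrationModel, EventSeries, PairingError,
                       compute_hr, compute_ptt, estimate_bp, fit_calibration,
                       match_beat_series, meg_ptt_bp, ptt_bp_pipeline)
from hemopulse.pttbp import PTTSeries, qc_ptt


def test_ptt_direct_subtraction():
    out = compute_ptt(EventSeries([1.0, 2.0]), EventSeries([1.12, 2.13]), (0.02, 0.4))
    np.testing.assert_allclose(out.ptt, [0.12, 0.13])
    assert out.n_unmatched == 0


def test_ptt_missing_distal_dropped():
    out = compute_ptt(EventSeries([1.0, 2.0, 3.0]), EventSeries([1.12, 3.13]), (0.02, 0.4))
    np.testing.assert_allclose(out.ptt, [0.12, 0.13])
    assert out.n_unmatched == 1


def test_ptt_pairing_error_on_mostly_unmatched():
    with pytest.raises(PairingError):
        compute_ptt(EventSeries(np.arange(1.0, 11.0)), EventSeries([1.1]), (0.02, 0.4))


def test_ptt_ambiguous_window_takes_earliest_and_flags():
    out = compute_ptt(EventSeries([1.0]), EventSeries([1.1, 1.3]), (0.02, 0.4))
    assert out.ptt[0] == pytest.approx(0.1)
    assert out.flagged[0]


@settings(max_examples=200, deadline=None)
@given(st.data())
def test_ptt_equals_naive_all_pairs_oracle(data):
    """Greedy windowed matching ≡ the naive sequential oracle."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    prox = np.unique(np.round(rng.uniform(0, 20, data.draw(st.integers(1, 15))), 3))
    dist = np.unique(np.round(rng.uniform(0, 20, data.draw(st.integers(1, 15))), 3))
    lo, hi = 0.02, 0.4

    # oracle: walk proximal beats in order, consume distal events once
    used = np.zeros(dist.size, bool)
    exp_t, exp_p = [], []
    for tp in prox:
        cand = [j for j in range(dist.size)
                if not used[j] and tp + lo <= dist[j] <= tp + hi
                and dist[j] >= (dist[np.flatnonzero(used)].max() if used.any() else -np.inf)]
        if not cand:
            continue
        j = cand[0]
        used[j] = True
        exp_t.append(tp)
        exp_p.append(dist[j] - tp)
    try:
        got = compute_ptt(EventSeries(prox), EventSeries(dist), (lo, hi))
    except PairingError:
        assert len(exp_t) <= 0.5 * prox.size
        return
    np.testing.assert_allclose(got.beat_times.times, exp_t)
    np.testing.assert_allclose(got.ptt, exp_p)


def test_ptt_against_simulator_truth(default_session):
    cfg, rec, gt = default_session
    _, ptt, _, _ = ptt_bp_pipeline(rec.channel("chest"), rec.channel("neck"))
    ia, ib = match_beat_series(ptt.beat_times.times, gt.beat_times.times, tol=0.1)
    assert ia.size >= 0.95 * gt.beat_times.n
    assert np.abs(ptt.ptt[ia] - gt.true_ptt[ib]).mean() <= 0.003


@pytest.mark.parametrize("period,bpm", [(0.8, 75.0), (1.0, 60.0)])
def test_hr_constant_rhythm(period, bpm):
    hr = compute_hr(EventSeries(np.arange(0.5, 30, period)))
    np.testing.assert_allclose(hr.bpm, bpm)
    assert hr.n == np.arange(0.5, 30, period).size - 1


def test_hr_tracks_simulated_variability(default_session):
    cfg, rec, gt = default_session
    bp, ptt, hr, _ = ptt_bp_pipeline(rec.channel("chest"), rec.channel("neck"))
    r = np.corrcoef(hr.bpm, gt.hr_at(hr.times))[0, 1]
    assert r >= 0.95


def test_calibration_exact_recovery():
    truth = CalibrationModel(A=700.0, alpha=1.0, B=40.0)
    ptt = np.linspace(5.0, 12.0, 40)
    model = fit_calibration(ptt, truth.predict(ptt), alpha=1.0)
    assert abs(model.A - 700.0) / 700.0 <= 1e-6
    assert abs(model.B - 40.0) / 40.0 <= 1e-6


def test_calibration_three_parameter_fit():
    truth = CalibrationModel(A=9.0, alpha=1.4, B=55.0)
    ptt = np.linspace(0.08, 0.2, 60)
    model = fit_calibration(ptt, truth.predict(ptt), fit_alpha=True)
    assert abs(model.alpha - 1.4) <= 1e-4
    assert abs(model.A - 9.0) / 9.0 <= 1e-4


def test_calibration_single_pair_fixed_A_solves_B():
    model = fit_calibration(np.array([0.1]), np.array([100.0]), alpha=1.0, A=7.2)
    assert model.B == pytest.approx(100.0 - 72.0)


def test_calibration_rejects_increasing_data():
    ptt = np.linspace(0.08, 0.2, 20)
    bp = 60 + 200 * ptt  # BP rising with PTT: unphysiological
    with pytest.raises(CalibrationError):
        fit_calibration(ptt, bp)


@settings(max_examples=100, deadline=None)
@given(A=st.floats(0.5, 1000), alpha=st.floats(0.2, 3), B=st.floats(0, 90))
def test_model_family_strictly_decreasing(A, alpha, B):
    model = CalibrationModel(A=A, alpha=alpha, B=B)
    p = np.linspace(*model.valid_ptt_range, 50)
    assert np.all(np.diff(model.predict(p)) < 0)
    # inverse round-trips on the valid range
    np.testing.assert_allclose(model.inverse(model.predict(p)), p, rtol=1e-9)


@settings(max_examples=50, deadline=None)
@given(A=st.floats(1.0, 20.0), B=st.floats(20.0, 60.0),
       seed=st.integers(0, 2**31 - 1))
def test_inverse_crime_parameter_identity(A, B, seed):
    """fit∘generate is the identity on (A, B) at zero noise."""
    rng = np.random.default_rng(seed)
    ptt = np.sort(rng.uniform(0.06, 0.3, 25))
    truth = CalibrationModel(A=A, alpha=1.0, B=B)
    model = fit_calibration(ptt, truth.predict(ptt), alpha=1.0)
    assert abs(model.A - A) / A <= 1e-6
    assert abs(model.B - B) / max(abs(B), 1.0) <= 1e-6


def test_estimate_bp_constant_and_scaling():
    beats = EventSeries(np.arange(1.0, 6.0))
    const = PTTSeries(beats, np.full(5, 0.1))
    model = CalibrationModel(A=7.2, alpha=1.0, B=40.0)
    out = estimate_bp(const, model)
    np.testing.assert_allclose(out.bp, 7.2 / 0.1 + 40.0)
    assert out.mode == "absolute" and out.units == "mmHg"
    # halving PTT doubles the A-term at alpha = 1
    halved = estimate_bp(PTTSeries(beats, np.full(5, 0.05)), model)
    np.testing.assert_allclose(halved.bp - 40.0, 2 * (out.bp - 40.0))


def test_estimate_bp_relative_sign_convention():
    beats = EventSeries(np.arange(1.0, 5.0))
    rising_ptt = PTTSeries(beats, np.array([0.10, 0.11, 0.12, 0.13]))
    out = estimate_bp(rising_ptt)
    assert out.mode == "relative" and out.units == "a.u."
    assert np.all(np.diff(out.bp) < 0)  # BP falls when PTT rises
    assert out.bp.mean() == pytest.approx(0.0, abs=1e-12)


def test_bp_recovery_from_simulator(default_session):
    cfg, rec, gt = default_session
    bp, _, _, _ = ptt_bp_pipeline(rec.channel("chest"), rec.channel("neck"))
    truth = np.interp(bp.beat_times.times, gt.bp.times, gt.bp.data)
    assert np.corrcoef(bp.bp, truth)[0, 1] >= 0.7


def test_meg_pipeline_matches_chest_pipeline(default_session):
    cfg, rec, gt = default_session
    bp_chest, _, _, _ = ptt_bp_pipeline(rec.channel("chest"), rec.channel("neck"))
    bp_meg, _, _, qc = meg_ptt_bp(rec.channel("meg"), rec.channel("neck"))
    ia, ib = match_beat_series(bp_chest.beat_times.times, bp_meg.beat_times.times)
    assert ia.size >= 50
    assert np.corrcoef(bp_chest.bp[ia], bp_meg.bp[ib])[0, 1] >= 0.8


def test_meg_zero_artifact_raises_pairing_error():
    import dataclasses
    from hemopulse import SimulationConfig, simulate_recording
    cfg = SimulationConfig(duration=60.0, seed=5, meg_artifact_amplitude=0.0)
    rec, _ = simulate_recording(cfg)
    with pytest.raises(PairingError):
        meg_ptt_bp(rec.channel("meg"), rec.channel("neck"))


def test_meg_noise_free_constant_offset(quiet_cfg):
    """Noise-free MEG PTT differs from chest PTT by the fixed artifact latency."""
    from hemopulse import simulate_recording
    rec, gt = simulate_recording(quiet_cfg)
    _, ptt_chest, _, _ = ptt_bp_pipeline(rec.channel("chest"), rec.channel("neck"))
    _, ptt_meg, _, _ = meg_ptt_bp(rec.channel("meg"), rec.channel("neck"))
    ia, ib = match_beat_series(ptt_chest.beat_times.times, ptt_meg.beat_times.times)
    offset = ptt_meg.ptt[ib] - ptt_chest.ptt[ia]
    np.testing.assert_allclose(offset, -quiet_cfg.meg_artifact_latency,
                               atol=2.0 / quiet_cfg.sample_rate)


def test_qc_ptt_drops_outliers():
    beats = EventSeries(np.arange(1.0, 21.0))
    p = np.full(20, 0.12)
    p[7] = 0.45  # inside bounds but a gross MAD outlier
    out, n = qc_ptt(PTTSeries(beats, p))
    assert n == 1 and out.n == 19
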