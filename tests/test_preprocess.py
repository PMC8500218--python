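import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, sosfreqz

import motionrca.preprocess as pp
from conftest import make_epochs
from motionrca.synth import (
    default_ground_truth,
    make_session_plan,
    simulate_behavior,
    simulate_eeg,
)

SFREQ = 500.0


# ---------------------------------------------------------------- filtering

def _tone_attenuation(freq_hz, n_sec=20.0):
    t = np.arange(int(n_sec * SFREQ)) / SFREQ
    x = np.sin(2 * np.pi * freq_hz * t)
    y = pp.bandpass_filter(x[None, :], SFREQ)[0]
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    return 1.0 - np.abs(y[mid]).max() / np.abs(x[mid]).max()


def test_passband_tone_passes():
    assert _tone_attenuation(10.0) < 0.01


def test_slow_drift_strongly_attenuated():
    # oracle: the designed filter's own frequency response at 0.05 Hz
    sos = butter(4, [0.3, 40.0], btype="bandpass", fs=SFREQ, output="sos")
    w, h = sosfreqz(sos, worN=[0.05, 60.0], fs=SFREQ)
    gain_005, gain_60 = np.abs(h) ** 2  # zero-phase: applied twice
    assert gain_005 < 0.1
    assert _tone_attenuation(0.05, n_sec=120.0) > 0.9


def test_stopband_tone_attenuated_per_design():
    sos = butter(4, [0.3, 40.0], btype="bandpass", fs=SFREQ, output="sos")
    _, h = sosfreqz(sos, worN=[60.0], fs=SFREQ)
    designed = 1.0 - np.abs(h[0]) ** 2
    measured = _tone_attenuation(60.0)
    assert measured > 0.9 and abs(measured - designed) < 0.03


def test_filter_band_validation():
    with pytest.raises(ValueError):
        pp.bandpass_filter(np.zeros((1, 100)), SFREQ, low_hz=0.3, high_hz=300.0)


# ------------------------------------------------------------ DC correction

def test_median_correction_examples():
    ep = make_epochs(np.full((2, 3, 10), 7.0))
    out = pp.dc_correct(ep)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-15)

    ep = make_epochs(np.array([[[1.0, 2.0, 100.0]]]))
    out = pp.dc_correct(ep)
    np.testing.assert_allclose(out.data[0, 0], [-1.0, 0.0, 98.0])
    assert np.nanmedian(out.data[0, 0]) == 0.0


def test_epoch_continuous_and_padding():
    raw = np.arange(40, dtype=float).reshape(2, 20)
    events = pd.DataFrame({"onset_sample": [0, 10], "duration_samples": [10, 5]})
    ep = pp.epoch_continuous(raw, events, SFREQ, channels=np.array([1, 2]))
    assert ep.data.shape == (2, 2, 10)
    assert ep.mask[1, :, 5:].all() and not ep.mask[1, :, :5].any()
    with pytest.raises(ValueError):
        bad = pd.DataFrame({"onset_sample": [15], "duration_samples": [10]})
        pp.epoch_continuous(raw, bad, SFREQ, channels=np.array([1, 2]))


# --------------------------------------------------------- bad electrodes

def _bad_electrode_fixture(montage):
    """127 quiet channels, one channel with exactly 20% large samples and
    one with 10%; pooled threshold sits between quiet and large values."""
    rng = np.random.default_rng(0)
    n_s = 400
    data = rng.uniform(-1.0, 1.0, size=(5, montage.n_channels, n_s))
    data[:, 10, :] = 0.5
    data[:, 10, : int(0.20 * n_s)] = 300.0   # 20% exceed -> flagged
    data[:, 20, :] = 0.5
    data[:, 20, : int(0.10 * n_s)] = 300.0   # 10% exceed -> kept
    return make_epochs(data)


def test_bad_electrode_threshold_semantics(montage):
    ep = _bad_electrode_fixture(montage)
    out, replaced = pp.detect_and_interpolate_bad_electrodes(ep, montage)
    assert replaced == [montage.channels[10]]


def test_interpolation_uses_neighbour_mean(montage):
    data = np.zeros((2, montage.n_channels, 50))
    ci = montage.index(75)
    neigh = montage.index(montage.neighbours(75, 6))
    data[:, neigh, :] = 5.0
    data[:, ci, : 25] = 1000.0   # 50% extreme samples
    ep = make_epochs(data)
    out, replaced = pp.detect_and_interpolate_bad_electrodes(ep, montage)
    assert montage.channels[ci] in replaced
    np.testing.assert_allclose(out.data[:, ci, :], 5.0)


def test_generator_injected_bad_channel_detected(montage):
    plan = simulate_behavior(
        make_session_plan("coherence", seed=1, n_per_level=6, n_catch=2, blocks=2),
        seed=1)
    gt = default_ground_truth(montage, bad_channel_prob=0.02,
                              bad_channel_sd_uv=300.0)
    ep, truth = simulate_eeg(plan, gt, seed=21, window_ms=(-200.0, 600.0))
    assert truth.bad_channels, "fixture needs at least one bad channel"
    _, replaced = pp.detect_and_interpolate_bad_electrodes(ep, montage)
    assert set(truth.bad_channels) <= set(replaced)


# ----------------------------------------------------------------- EOG

def test_pure_eog_mixture_channel_zeroed(montage):
    rng = np.random.default_rng(2)
    data = rng.normal(size=(3, montage.n_channels, 200))
    heog, veog = pp.eog_signals(make_epochs(data), montage)
    target = montage.index(40)
    data[:, target, :] = 0.5 * heog - 0.25 * veog + 3.0
    out = pp.regress_out_eog(make_epochs(data), montage)
    np.testing.assert_allclose(out.data[:, target, :], 0.0, atol=1e-10)


def test_orthogonal_channel_unchanged(montage):
    n_s = 400
    data = np.zeros((1, montage.n_channels, n_s))
    t = np.arange(n_s)
    for role, val in (("heog_right", 1.0), ("heog_left", -1.0)):
        data[:, montage.role_indices(role), :] = val * np.sin(2 * np.pi * t / 50)
    target = montage.index(40)
    orth = np.cos(2 * np.pi * t / 50)   # orthogonal to the sine over full periods
    data[:, target, :] = orth
    out = pp.regress_out_eog(make_epochs(data), montage)
    np.testing.assert_allclose(out.data[0, target], orth, atol=1e-8)


def test_eog_regression_matches_normal_equations(montage):
    rng = np.random.default_rng(3)
    data = rng.normal(size=(2, montage.n_channels, 30))
    ep = make_epochs(data)
    heog, veog = pp.eog_signals(ep, montage)
    out = pp.regress_out_eog(ep, montage)
    target = montage.index(55)
    X = np.column_stack([heog.ravel(), veog.ravel(), np.ones(heog.size)])
    y = data[:, target, :].ravel()
    beta = np.linalg.solve(X.T @ X, X.T @ y)   # brute-force 3x3 solve
    np.testing.assert_allclose(out.data[:, target, :].ravel(), y - X @ beta,
                               atol=1e-10)


def test_constant_eog_skipped_with_warning(montage):
    ep = make_epochs(np.ones((2, montage.n_channels, 20)))
    with pytest.warns(UserWarning):
        out = pp.regress_out_eog(ep, montage)
    np.testing.assert_array_equal(out.data, ep.data)


# ----------------------------------------------- trial masking / transients

def test_trial_channel_rule_boundary_inclusive():
    n_s = 100
    data = np.random.default_rng(4).uniform(-1, 1, size=(4, 8, n_s))
    data[0, 3, :15] = 50.0    # exactly 15% -> masked ("15% or more")
    data[1, 4, :14] = 50.0    # 14% -> kept
    ep = make_epochs(data)
    out = pp.mask_trial_channels(ep, threshold=10.0)
    assert out.mask[0, 3].all()
    assert not out.mask[1, 4].any()


def test_all_zero_data_nothing_masked():
    ep = make_epochs(np.zeros((3, 4, 50)))
    out = pp.mask_trial_channels(ep, threshold=10.0)
    assert not out.mask.any()
    out2 = pp.remove_transients(ep)
    assert not out2.mask.any()      # zero-variance: no masking


def test_transient_boundary_and_injection():
    rng = np.random.default_rng(5)
    data = rng.standard_normal((10, 2, 500))
    # analytic fixture on channel 1: known mean/SD via direct construction
    spike_val = float(np.nanmean(data[:, 0]) + 10 * np.nanstd(data[:, 0]))
    data[3, 0, 100] = spike_val
    ep = make_epochs(data)
    out = pp.remove_transients(ep, sd_threshold=4.0)
    assert out.mask[3, 0, 100]
    # boundary semantics: a sample at exactly 4 SD is masked
    x = np.zeros((1, 1, 1000))
    base = np.tile([1.0, -1.0], 500)
    x[0, 0] = base
    sd = x[0, 0].std()
    x[0, 0, 0] = x[0, 0].mean() + 4.0 * sd
    out2 = pp.remove_transients(make_epochs(x), sd_threshold=4.0)
    # recompute: injected value shifts mean/sd; use the stage's own stats
    mean, s = np.nanmean(x), np.nanstd(x)
    expected = np.abs(x[0, 0] - mean) >= 4.0 * s
    np.testing.assert_array_equal(out2.mask[0, 0], expected)


# ------------------------------------------------------------- rejection

def test_trial_rejection_threshold_is_strict():
    data = np.random.default_rng(6).normal(size=(3, 128, 50))
    mask = np.zeros_like(data, dtype=bool)
    mask[0, :20, :] = True    # 15.6% of channels -> dropped
    mask[1, :19, :] = True    # 14.8% -> kept
    ep = make_epochs(data, mask=mask)
    out, dropped = pp.reject_trials(ep, frac=0.15)
    assert dropped.tolist() == [True, False, False]
    assert out.n_trials == 2


def test_all_trials_rejected_raises():
    data = np.zeros((2, 10, 5))
    mask = np.ones_like(data, dtype=bool)
    ep = make_epochs(data, mask=mask)
    with pytest.raises(ValueError):
        pp.reject_trials(ep)


# -------------------------------------------------- reference and baseline

def test_average_reference_and_baseline_identities():
    rng = np.random.default_rng(7)
    data = rng.normal(size=(4, 16, 250)) + 3.0
    ep = make_epochs(data, time0_ms=-100.0)
    out = pp.rereference_and_baseline(ep)
    np.testing.assert_allclose(np.nanmean(out.data, axis=1), 0.0, atol=1e-12)
    sel = (out.time_ms >= -100.0) & (out.time_ms < 0.0)
    np.testing.assert_allclose(np.nanmean(out.data[:, :, sel], axis=2), 0.0,
                               atol=1e-12)


def test_constant_offset_trial_becomes_zero():
    data = np.full((1, 8, 100), 42.0)
    out = pp.rereference_and_baseline(make_epochs(data, time0_ms=-100.0))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_flat_channels_detected():
    data = np.random.default_rng(8).normal(size=(3, 6, 40))
    data[:, 2, :] = 1.5
    ep = make_epochs(data)
    assert pp.find_flat_channels(ep) == [3]


# ------------------------------------------------------------- full chain

def test_full_chain_deterministic_and_reports(montage):
    plan = simulate_behavior(
        make_session_plan("coherence", seed=9, n_per_level=4, n_catch=2, blocks=2),
        seed=9)
    gt = default_ground_truth(montage, bad_channel_prob=0.02, transient_prob=2e-5)
    ep, _ = simulate_eeg(plan, gt, seed=10, window_ms=(-200.0, 600.0))
    with pytest.warns(UserWarning):
        a, rep_a = pp.preprocess_epochs(ep, montage)
        b, rep_b = pp.preprocess_epochs(ep, montage)
    np.testing.assert_array_equal(np.nan_to_num(a.data), np.nan_to_num(b.data))
    np.testing.assert_array_equal(a.mask, b.mask)
    assert 0.0 <= rep_a.percent_trials_removed <= 100.0
    assert rep_a.percent_electrodes_replaced == rep_b.percent_electrodes_replaced
    assert a.reference == "average"
    # masking only grows except declared interpolation: trials out <= in
    assert rep_a.n_trials_out <= rep_a.n_trials_in


def test_injected_artifact_recall(montage):
    """High-amplitude injected artifacts are caught by the chain."""
    plan = simulate_behavior(
        make_session_plan("coherence", seed=11, n_per_level=6, n_catch=2, blocks=2),
        seed=11)
    gt = default_ground_truth(montage, bad_channel_prob=0.03,
                              bad_channel_sd_uv=400.0, transient_prob=3e-5,
                              transient_amp_uv=700.0)
    ep, truth = simulate_eeg(plan, gt, seed=12, window_ms=(-200.0, 600.0))
    x = pp.dc_correct(pp.bandpass_filter(ep))
    thr = pp.amplitude_threshold(x)
    _, replaced = pp.detect_and_interpolate_bad_electrodes(x, montage, threshold=thr)
    assert set(truth.bad_channels) <= set(replaced)
    masked = pp.remove_transients(x).mask
    hits = sum(bool(masked[t, c, max(0, s - 2): s + 3].any())
               for t, c, s in truth.transient_index)
    assert truth.transient_index.shape[0] > 0
    assert hits / truth.transient_index.shape[0] >= 0.95
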