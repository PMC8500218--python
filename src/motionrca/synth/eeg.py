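"""Synthetic evoked EEG with known ground truth.

Each simulated trial is a linear mixture

    x_c(t) = sum_k  a_ck * g_k * s_k(t)  +  spatially correlated noise
             +  EOG leakage  +  injected artifacts

where ``a_k`` are fixed unit-norm scalp topographies, ``s_k(t)`` are the
condition/group-specific component time courses and ``g_k`` are
trial-specific Gaussian amplitude gains (the source of trial-to-trial
unreliability that RCA exploits).  Two components are injected:

* an *occipital* component carrying the motion-onset morphology: small
  negativity ~60 ms, P1-like positivity ~100 ms, N2-like negativity
  ~160 ms and a P2-like positivity ~240-300 ms (the P2 amplitude carries
  the difficulty effect);
* a *centro-parietal* component with an early auditory-cue bump and a
  late decision-like ramp.

Artifacts emulate what the preprocessing chain must remove: whole-session
bad channels (high-amplitude noise), sparse transient spikes, and EOG
leakage consistent with the montage's EOG role electrodes.  The full
realization (clean component time courses, gains, bad channels, transient
locations) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ..epochs import EpochSet
from ..montage import Montage
from .design import MAX_STIMULUS_MS, SessionPlan

COMPONENT_NAMES = ("centroparietal", "occipital")


def _bump(t: np.ndarray, mu: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _cosine_window(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Raised-cosine window equal to 1 on the middle half of [t0, t1]."""
    w = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    u = (t[inside] - t0) / (t1 - t0)
    w[inside] = np.minimum(1.0, 2.0 * np.sin(np.pi * u))  # Tukey-style tapered box
    return w


@dataclass
class GroundTruth:
    """Everything the generator needs, and recovery tests check against."""

    montage: Montage
    topographies: np.ndarray                  # (n_channels, 2), unit columns
    n2_amp_uv: float = -5.0
    n2_latency_ms: float = 160.0
    p1_amp_uv: float = 4.0
    p2_amp_uv: dict = field(default_factory=lambda: {"easy": 3.5, "difficult": 2.3, "catch": 3.8})
    cpp_amp_uv: dict = field(default_factory=lambda: {"easy": 6.0, "difficult": 5.0, "catch": 6.2})
    cpp_center_ms: dict = field(default_factory=lambda: {"easy": 380.0, "difficult": 430.0, "catch": 360.0})
    #: trial-to-trial amplitude jitter SD per component (centro-parietal,
    #: occipital); unequal values separate the components' reliabilities
    gain_jitter_sd: tuple = (0.1, 0.45)
    noise_sd_uv: float = 2.5                  # per-channel noise SD
    noise_spatial_scale: float = 0.5          # chord-distance kernel length
    noise_smooth_samples: float = 2.0         # temporal smoothing of the noise
    eog_gain_uv: float = 1.0                  # scales the EOG leakage field
    blink_rate_hz: float = 0.2
    bad_channel_prob: float = 0.0
    bad_channel_sd_uv: float = 120.0
    transient_prob: float = 0.0
    transient_amp_uv: float = 150.0
    #: additive group offsets: {(group, component_name): (t0_ms, t1_ms, delta_uv)}
    group_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.topographies = np.asarray(self.topographies, dtype=float)
        if self.topographies.shape != (self.montage.n_channels, 2):
            raise ValueError("topographies must be channels x 2")
        if np.linalg.matrix_rank(self.topographies) < 2:
            raise ValueError("topographies must be linearly independent")
        self.topographies /= np.linalg.norm(self.topographies, axis=0, keepdims=True)
        self.gain_jitter_sd = np.broadcast_to(
            np.asarray(self.gain_jitter_sd, dtype=float), (2,)
        ).copy()


def _gaussian_topography(montage: Montage, center_channel: int, scale: float) -> np.ndarray:
    c = montage.positions[montage.index(center_channel)]
    d = np.linalg.norm(montage.positions - c, axis=1)
    a = np.exp(-((d / scale) ** 2))
    return a / np.linalg.norm(a)


def default_ground_truth(montage: Montage, **overrides) -> GroundTruth:
    """Occipital topography centred on Oz (E75), centro-parietal on E62 (Pz)."""
    topo = np.column_stack(
        [_gaussian_topography(montage, 62, 0.35), _gaussian_topography(montage, 75, 0.40)]
    )
    return GroundTruth(montage=montage, topographies=topo, **overrides)


def evoked_timecourses(
    gt: GroundTruth, time_ms: np.ndarray, task: str, difficulty: str, group: str = "TD"
) -> np.ndarray:
    """Noise-free component time courses, shape ``(2, n_samples)`` in µV.

    Index 0 is the centro-parietal component, index 1 the occipital one,
    matching :data:`COMPONENT_NAMES`.
    """
    t = np.asarray(time_ms, dtype=float)
    occ = (
        _bump(t, 60.0, 12.0, -0.5)
        + _bump(t, 100.0, 22.0, gt.p1_amp_uv)
        + _bump(t, gt.n2_latency_ms, 26.0, gt.n2_amp_uv)
        + _bump(t, 270.0, 55.0, gt.p2_amp_uv[difficulty])
    )
    c = gt.cpp_center_ms[difficulty]
    ramp = gt.cpp_amp_uv[difficulty] / (1.0 + np.exp(-(t - c) / 90.0))
    ramp *= np.exp(-np.clip(t - (c + 280.0), 0, None) / 350.0)  # post-peak decay
    cpp = _bump(t, 180.0, 30.0, 1.2) + ramp
    out = np.vstack([cpp, occ])
    for (g, comp), (t0, t1, delta) in gt.group_effects.items():
        if g == group:
            out[COMPONENT_NAMES.index(comp)] += delta * _cosine_window(t, t0, t1)
    return out


@dataclass
class SimTruth:
    """Realized ground truth for one simulated session."""

    component_timecourses: np.ndarray  # (n_trials, 2, n_samples), gains applied
    gains: np.ndarray                  # (n_trials, 2)
    bad_channels: list                 # 1-based channel numbers
    transient_index: np.ndarray        # (n, 3): trial, channel index, sample
    topographies: np.ndarray           # (n_channels, 2)


def _correlated_noise(rng, chol, n_samples, sd, smooth):
    white = rng.standard_normal((chol.shape[0], n_samples))
    if smooth > 0:
        white = gaussian_filter1d(white, smooth, axis=1)
        white /= max(white.std(), 1e-12)
    return sd * (chol @ white)


def _eog_gains(montage: Montage) -> tuple[np.ndarray, np.ndarray]:
    eye = montage.positions[montage.role_indices("veog_lower")].mean(axis=0)
    d = np.linalg.norm(montage.positions - eye, axis=1)
    leak = 0.4 * np.exp(-((d / 0.6) ** 2))
    veog = leak.copy()
    veog[montage.role_indices("veog_upper")] = 1.0
    veog[montage.role_indices("veog_lower")] = -1.0
    heog = 0.5 * leak
    heog[montage.role_indices("heog_right")] = 1.0
    heog[montage.role_indices("heog_left")] = -1.0
    return heog, veog


def simulate_eeg(
    plan: SessionPlan,
    gt: GroundTruth,
    seed: int = 0,
    group: str = "TD",
    participant: str = "P000",
    window_ms: tuple[float, float] = (-2000.0, 1000.0),
    sfreq: float = 500.0,
) -> tuple[EpochSet, SimTruth]:
    """Generate a vertex-referenced session of epochs for one participant.

    The time axis is stimulus-locked; samples before a trial's own
    fixation onset or after its offset-period end are masked as missing.
    A pure function of ``(plan, gt, seed)``.
    """
    rng = np.random.default_rng(seed)
    montage = gt.montage
    n_ch = montage.n_channels
    dt = 1000.0 / sfreq
    time_ms = np.arange(window_ms[0], window_ms[1], dt)
    n_s = len(time_ms)
    n_t = plan.n_trials

    # spatial noise covariance from electrode geometry
    if gt.noise_sd_uv > 0:
        dmat = np.linalg.norm(
            montage.positions[:, None, :] - montage.positions[None, :, :], axis=2
        )
        cov = np.exp(-((dmat / gt.noise_spatial_scale) ** 2))
        chol = np.linalg.cholesky(cov + 1e-8 * np.eye(n_ch))
    else:
        chol = np.zeros((n_ch, n_ch))

    heog_gain, veog_gain = _eog_gains(montage)

    role_idx = np.concatenate([montage.role_indices(r) for r in montage.roles])
    bad = (rng.random(n_ch) < gt.bad_channel_prob)
    bad[role_idx] = False
    bad_idx = np.where(bad)[0]

    base_cache: dict[str, np.ndarray] = {}
    data = np.empty((n_t, n_ch, n_s))
    mask = np.zeros((n_t, n_ch, n_s), dtype=bool)
    clean = np.empty((n_t, 2, n_s))
    gains = np.empty((n_t, 2))
    transients: list[tuple[int, int, int]] = []

    for i, tr in enumerate(plan.trials):
        if tr.difficulty not in base_cache:
            base_cache[tr.difficulty] = evoked_timecourses(
                gt, time_ms, plan.task, tr.difficulty, group
            )
        g = 1.0 + gt.gain_jitter_sd * rng.standard_normal(2)  # per-component gains
        gains[i] = g
        clean[i] = g[:, None] * base_cache[tr.difficulty]
        x = gt.topographies @ clean[i]

        if gt.noise_sd_uv > 0:
            x = x + _correlated_noise(rng, chol, n_s, gt.noise_sd_uv, gt.noise_smooth_samples)

        if gt.eog_gain_uv > 0:
            drift_v = gaussian_filter1d(rng.standard_normal(n_s), 25.0) * 60.0
            drift_h = gaussian_filter1d(rng.standard_normal(n_s), 25.0) * 40.0
            # blink centres may straddle the epoch edges, keeping the
            # expected blink profile stationary over the window
            pad = 200.0
            span = (time_ms[-1] + pad) - (time_ms[0] - pad)
            n_blinks = rng.poisson(gt.blink_rate_hz * span / 1000.0)
            for _ in range(n_blinks):
                mu = rng.uniform(time_ms[0] - pad, time_ms[-1] + pad)
                drift_v += _bump(time_ms, mu, 50.0, rng.uniform(100.0, 200.0))
            x = x + gt.eog_gain_uv * (np.outer(veog_gain, drift_v) + np.outer(heog_gain, drift_h))

        if bad_idx.size:
            x[bad_idx] = rng.normal(0.0, gt.bad_channel_sd_uv, size=(bad_idx.size, n_s))

        # valid span: fixation onset .. end of offset period
        start = -(tr.fixation_ms + tr.random_ms)
        stim_end = tr.rt_ms if tr.rt_ms is not None else MAX_STIMULUS_MS
        end = stim_end + tr.offset_ms
        mask[i] = (time_ms < start) | (time_ms >= end)

        if gt.transient_prob > 0:
            hits = (rng.random((n_ch, n_s)) < gt.transient_prob) & ~mask[i]
            hits[bad_idx] = False   # bad channels are already pure noise
            cc, ss = np.where(hits)
            amp = rng.choice([-1.0, 1.0], size=cc.size) * gt.transient_amp_uv * rng.uniform(
                1.0, 2.0, size=cc.size
            )
            x[cc, ss] += amp
            transients += [(i, int(c), int(s)) for c, s in zip(cc, ss)]

        data[i] = x

    trials = plan.to_frame()
    trials["participant"] = participant
    trials["group"] = group
    epochs = EpochSet(
        data=data, mask=mask, time_ms=time_ms, channels=montage.channels.copy(),
        trials=trials, sfreq=sfreq, reference="vertex", locking="stimulus",
    )
    truth = SimTruth(
        component_timecourses=clean, gains=gains,
        bad_channels=montage.channels[bad_idx].tolist(),
        transient_index=np.array(transients, dtype=int).reshape(-1, 3),
        topographies=gt.topographies.copy(),
    )
    return epochs, truth


def make_component_recovery_data(
    montage: Montage,
    seed: int = 0,
    n_trials: int = 60,
    snr: float = 0.5,
    reliabilities: tuple[float, float] = (0.75, 0.25),
    n_samples: int = 350,
) -> tuple[EpochSet, np.ndarray]:
    """Two-component benchmark for spatial-filter recovery.

    Trial-to-trial reliability of an injected component — the ratio of
    across-trial to within-trial covariance along its direction — is
    ``mu^2 / (mu^2 + sigma_g^2)`` for trial gains ``N(mu=1, sigma_g)``,
    so per-component gain SDs are chosen to realize the requested
    reliabilities (default 3:1).  The two time courses are orthogonalized
    over the epoch so cross-component covariance terms vanish and the
    generalized eigenvectors identify the true mixing columns.  White
    sensor noise is scaled so that total signal variance over all
    channels equals ``snr`` times the noise variance.  Returns the epochs
    and the true topographies (more reliable component first).
    """
    r = np.asarray(reliabilities, dtype=float)
    if not ((0 < r) & (r < 1)).all() or r[0] <= r[1]:
        raise ValueError("need 1 > r1 > r2 > 0")
    gain_sd = np.sqrt(1.0 / r - 1.0)
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * 2.0 - 100.0
    s = np.vstack([
        _bump(t, 150.0, 40.0, 1.0) + _bump(t, 380.0, 80.0, 0.8),
        _bump(t, 250.0, 50.0, 1.0) - _bump(t, 90.0, 30.0, 0.7),
    ])
    s[1] -= (s[1] @ s[0]) / (s[0] @ s[0]) * s[0]   # temporal orthogonality
    s /= s.std(axis=1, keepdims=True)
    topo = np.column_stack(
        [_gaussian_topography(montage, 62, 0.45), _gaussian_topography(montage, 75, 0.40)]
    )
    gains = 1.0 + gain_sd[None, :] * rng.standard_normal((n_trials, 2))
    clean = np.einsum("ck,nk,ks->ncs", topo, gains, s)
    noise_sd = np.sqrt(clean.var() / snr)
    data = clean + noise_sd * rng.standard_normal(clean.shape)
    trials = pd.DataFrame({"trial": np.arange(n_trials)})
    epochs = EpochSet(
        data=data, mask=np.zeros_like(data, dtype=bool), time_ms=t,
        channels=montage.channels.copy(), trials=trials,
    )
    return epochs, topo
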