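"""Artifact-rejection and referencing chain for epoched EEG.

The stages run in a fixed order, mirroring the acquisition pipeline the
analysis was designed for:

1. zero-phase 0.3-40 Hz band-pass (4th-order Butterworth),
2. epoching (if needed) and per-trial/channel median DC correction,
3. session-level bad-electrode detection (channels with 15% or more
   samples above the participant's pooled 97.5th absolute-amplitude
   percentile) and replacement by the mean of nearest neighbours,
4. linear regression of the horizontal and vertical EOG out of every
   channel (HEOG = E125 - E128; VEOG = (E8 + E25) - (E126 + E127)),
5. trial-by-trial channel removal with the same 15%-or-more rule,
6. substitution of transients (samples four or more SDs from the
   channel mean) with missing values,
7. rejection of trials in which *more than* 15% of channels were
   removed (note the strict inequality, unlike the channel rules),
8. removal of flat (zero-variance) channels,
9. average re-reference over available channels,
10. baseline to the mean of the last 100 ms of the random-motion period.

Masking operations only ever grow the missing mask; the single declared
exception is bad-electrode interpolation, which fills flagged channels
from their neighbours.  The whole chain is deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .epochs import EpochSet
from .montage import Montage


@dataclass
class PreprocessConfig:
    bandpass_hz: tuple[float, float] = (0.3, 40.0)
    filter_order: int = 4
    bad_electrode_sample_frac: float = 0.15
    amplitude_percentile: float = 97.5
    transient_sd: float = 4.0
    trial_channel_frac: float = 0.15
    trial_reject_channel_frac: float = 0.15
    baseline_ms: float = 100.0
    n_neighbours_for_interpolation: int = 6

    def __post_init__(self) -> None:
        for f in (self.bad_electrode_sample_frac, self.trial_channel_frac,
                  self.trial_reject_channel_frac):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")
        if not 0.0 < self.amplitude_percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")


@dataclass
class PreprocessReport:
    percent_electrodes_replaced: float = 0.0
    percent_trial_channels_removed: float = 0.0
    percent_trials_removed: float = 0.0
    replaced_electrodes: list = field(default_factory=list)
    flat_channels: list = field(default_factory=list)
    n_trials_in: int = 0
    n_trials_out: int = 0
    amplitude_threshold_uv: float = float("nan")
    logs: list = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.logs.append(msg)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------- filtering

def bandpass_filter(
    data: np.ndarray | EpochSet,
    sfreq: float | None = None,
    low_hz: float = 0.3,
    high_hz: float = 40.0,
    order: int = 4,
) -> np.ndarray | EpochSet:
    """Zero-phase Butterworth band-pass along the time axis.

    Accepts a raw array (time on the last axis) or an :class:`EpochSet`;
    masked samples are zero-filled for filtering and re-masked after.
    """
    if isinstance(data, EpochSet):
        out = data.copy()
        filled = np.where(out.mask, 0.0, out.data)
        out.data = bandpass_filter(filled, out.sfreq, low_hz, high_hz, order)
        out.data[out.mask] = np.nan
        return out
    if sfreq is None:
        raise ValueError("sfreq required for array input")
    nyq = sfreq / 2.0
    if not 0.0 < low_hz < high_hz < nyq:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=sfreq, output="sos")
    return sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


# ---------------------------------------------------------------- epoching

def epoch_continuous(
    raw: np.ndarray,
    events: pd.DataFrame,
    sfreq: float,
    channels: np.ndarray,
    time0_ms: float = 0.0,
) -> EpochSet:
    """Cut a continuous ``channels x samples`` record into epochs.

    ``events`` needs ``onset_sample`` and ``duration_samples`` columns;
    epochs shorter than the longest one are padded with missing values.
    """
    n_max = int(events["duration_samples"].max())
    n_ch = raw.shape[0]
    data = np.full((len(events), n_ch, n_max), np.nan)
    mask = np.ones((len(events), n_ch, n_max), dtype=bool)
    for i, row in enumerate(events.itertuples(index=False)):
        o, n = int(row.onset_sample), int(row.duration_samples)
        if o < 0 or o + n > raw.shape[1]:
            raise ValueError(f"event {i} outside the recording")
        data[i, :, :n] = raw[:, o:o + n]
        mask[i, :, :n] = False
    time_ms = time0_ms + np.arange(n_max) * 1000.0 / sfreq
    return EpochSet(data=data, mask=mask, time_ms=time_ms, channels=channels,
                    trials=events.reset_index(drop=True), sfreq=sfreq)


def dc_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial x channel median over the epoch (DC offset)."""
    out = epochs.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(out.data, axis=2, keepdims=True)
    out.data = out.data - np.where(np.isnan(med), 0.0, med)
    out.data[out.mask] = np.nan
    return out


def epoch_and_dc_correct(raw, events=None, sfreq: float = 500.0,
                         channels=None, time0_ms: float = 0.0) -> EpochSet:
    if isinstance(raw, EpochSet):
        return dc_correct(raw)
    return dc_correct(epoch_continuous(raw, events, sfreq, channels, time0_ms))


# ------------------------------------------------------------- thresholding

def amplitude_threshold(epochs: EpochSet, percentile: float = 97.5) -> float:
    """Participant-level absolute-amplitude percentile, pooled over all
    channels, trials and unmasked samples of the session."""
    vals = np.abs(epochs.data[epochs.valid()])
    if vals.size == 0:
        raise ValueError("no valid samples")
    return float(np.percentile(vals, percentile))


def _exceed_frac(data, valid, thr, axis):
    exceed = (np.abs(np.where(valid, data, 0.0)) > thr) & valid
    n = valid.sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, exceed.sum(axis=axis) / np.maximum(n, 1), 0.0)


def detect_and_interpolate_bad_electrodes(
    epochs: EpochSet,
    montage: Montage,
    config: PreprocessConfig | None = None,
    threshold: float | None = None,
) -> tuple[EpochSet, list]:
    """Flag channels with >= 15% of session samples above the pooled
    percentile threshold and replace them, everywhere, by the mean of
    their nearest non-flagged neighbours."""
    config = config or PreprocessConfig()
    thr = amplitude_threshold(epochs, config.amplitude_percentile) if threshold is None else threshold
    frac = _exceed_frac(epochs.data, epochs.valid(), thr, axis=(0, 2))  # per channel
    flagged = np.where(frac >= config.bad_electrode_sample_frac)[0]
    out = epochs.copy()
    flagged_set = set(flagged.tolist())
    for ci in flagged:
        order = montage._neighbour_order[ci]
        good = [j for j in order if j not in flagged_set][: config.n_neighbours_for_interpolation]
        if not good:
            raise ValueError("all neighbours of a flagged channel are flagged")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            repl = np.nanmean(epochs.data[:, good, :], axis=1)
        out.data[:, ci, :] = repl
        out.mask[:, ci, :] = np.isnan(repl)
    out.data[out.mask] = np.nan
    return out, epochs.channels[flagged].tolist()


# ---------------------------------------------------------------- EOG

def eog_signals(epochs: EpochSet, montage: Montage) -> tuple[np.ndarray, np.ndarray]:
    """Derived HEOG and VEOG time courses, shape ``(n_trials, n_samples)``."""
    d = epochs.data

    def chan(role):
        return d[:, montage.role_indices(role), :].sum(axis=1)

    heog = chan("heog_right") - chan("heog_left")
    veog = chan("veog_upper") - chan("veog_lower")
    return heog, veog


def regress_out_eog(epochs: EpochSet, montage: Montage) -> EpochSet:
    """OLS-remove [HEOG, VEOG, intercept] from every channel.

    The fit uses all retained (unmasked) samples of the session for each
    channel; residuals replace the data.  Constant regressors trigger a
    warning and a no-op.
    """
    heog, veog = eog_signals(epochs, montage)
    eog_valid = np.isfinite(heog) & np.isfinite(veog)
    if np.nanstd(heog[eog_valid]) < 1e-12 or np.nanstd(veog[eog_valid]) < 1e-12:
        warnings.warn("EOG regressors are constant; skipping EOG regression")
        return epochs.copy()
    out = epochs.copy()
    X = np.column_stack([heog.ravel(), veog.ravel(), np.ones(heog.size)])
    for ci in range(epochs.n_channels):
        y = epochs.data[:, ci, :].ravel()
        rows = np.isfinite(y) & eog_valid.ravel()
        if rows.sum() < 4:
            continue
        beta, *_ = np.linalg.lstsq(X[rows], y[rows], rcond=None)
        resid = y - X @ beta
        out.data[:, ci, :] = resid.reshape(epochs.n_trials, epochs.n_samples)
    out.data[out.mask] = np.nan
    return out


# ------------------------------------------------------- per-trial masking

def mask_trial_channels(
    epochs: EpochSet,
    config: PreprocessConfig | None = None,
    threshold: float | None = None,
) -> EpochSet:
    """Mask (trial, channel) pairs with >= 15% samples above threshold."""
    config = config or PreprocessConfig()
    thr = amplitude_threshold(epochs, config.amplitude_percentile) if threshold is None else threshold
    frac = _exceed_frac(epochs.data, epochs.valid(), thr, axis=2)  # (trials, channels)
    bad = frac >= config.trial_channel_frac
    out = epochs.copy()
    out.set_missing(bad[:, :, None] & np.ones(epochs.n_samples, dtype=bool))
    return out


def remove_transients(epochs: EpochSet, sd_threshold: float = 4.0) -> EpochSet:
    """Mask samples four or more SDs from the channel's session mean."""
    out = epochs.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(epochs.data, axis=(0, 2))
        sd = np.nanstd(epochs.data, axis=(0, 2))
    ok = np.isfinite(sd) & (sd > 0)
    dev = np.abs(epochs.data - np.where(np.isfinite(mean), mean, 0.0)[None, :, None])
    hits = ok[None, :, None] & epochs.valid() & (
        dev >= sd_threshold * np.where(ok, sd, np.inf)[None, :, None]
    )
    out.set_missing(hits)
    return out


def reject_trials(
    epochs: EpochSet, frac: float = 0.15
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials in which *more than* ``frac`` of channels were removed.

    A channel counts as removed in a trial when it is fully masked there.
    Returns the reduced set and the boolean drop indicator per trial.
    """
    removed = epochs.mask.all(axis=2)  # (trials, channels)
    drop = removed.mean(axis=1) > frac
    if drop.all():
        raise ValueError("all trials rejected; inspect the data and thresholds")
    return epochs.select_trials(np.where(~drop)[0]), drop


def find_flat_channels(epochs: EpochSet) -> list:
    """Channels with zero variance over the whole session (dead sensors)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(epochs.data, axis=(0, 2))
    flat = np.isfinite(sd) & (sd == 0.0)
    return epochs.channels[flat].tolist()


# ------------------------------------------------- reference and baseline

def rereference_and_baseline(
    epochs: EpochSet, baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
) -> EpochSet:
    """Average-reference over available channels, then subtract the mean
    of the pre-stimulus baseline window per trial and channel."""
    out = epochs.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmean(out.data, axis=1, keepdims=True)
    out.data = out.data - np.where(np.isnan(ref), 0.0, ref)
    out.reference = "average"

    sel = (out.time_ms >= baseline_window_ms[0]) & (out.time_ms < baseline_window_ms[1])
    if not sel.any():
        raise ValueError("baseline window outside the epoch")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(out.data[:, :, sel], axis=2, keepdims=True)
    missing_base = ~np.isfinite(base)
    if missing_base.any():
        warnings.warn("baseline window fully masked for some trial x channel")
        out.trials = out.trials.copy()
        out.trials["baseline_missing"] = missing_base.any(axis=(1, 2))
    out.data = out.data - np.where(missing_base, 0.0, base)
    out.data[out.mask] = np.nan
    return out


# ----------------------------------------------------------- full chain

def preprocess_epochs(
    epochs: EpochSet,
    montage: Montage,
    config: PreprocessConfig | None = None,
) -> tuple[EpochSet, PreprocessReport]:
    """Run the full preprocessing chain in its fixed order."""
    config = config or PreprocessConfig()
    rep = PreprocessReport(n_trials_in=epochs.n_trials)

    x = bandpass_filter(epochs, low_hz=config.bandpass_hz[0],
                        high_hz=config.bandpass_hz[1], order=config.filter_order)
    rep.log("band-pass filtered")
    x = dc_correct(x)
    rep.log("median DC correction")

    thr = amplitude_threshold(x, config.amplitude_percentile)
    rep.amplitude_threshold_uv = thr

    x, replaced = detect_and_interpolate_bad_electrodes(x, montage, config, threshold=thr)
    rep.replaced_electrodes = replaced
    rep.percent_electrodes_replaced = 100.0 * len(replaced) / x.n_channels
    rep.log(f"replaced {len(replaced)} bad electrodes")

    x = regress_out_eog(x, montage)
    rep.log("EOG regressed out")

    before = x.mask.all(axis=2).sum()
    x = mask_trial_channels(x, config, threshold=thr)
    pairs = x.mask.all(axis=2).sum() - before
    rep.percent_trial_channels_removed = 100.0 * pairs / (x.n_trials * x.n_channels)
    rep.log(f"masked {pairs} trial-channel pairs")

    x = remove_transients(x, config.transient_sd)
    rep.log("transients substituted with missing values")

    x, dropped = reject_trials(x, config.trial_reject_channel_frac)
    rep.percent_trials_removed = 100.0 * dropped.mean()
    rep.n_trials_out = x.n_trials
    rep.log(f"rejected {int(dropped.sum())} trials")

    rep.flat_channels = find_flat_channels(x)
    if rep.flat_channels:
        flat_idx = [int(np.where(x.channels == c)[0][0]) for c in rep.flat_channels]
        w = np.zeros(x.mask.shape, dtype=bool)
        w[:, flat_idx, :] = True
        x.set_missing(w)
        rep.log(f"removed flat channels {rep.flat_channels}")

    x = rereference_and_baseline(x, (-config.baseline_ms, 0.0))
    rep.log("average reference and baseline applied")
    return x, rep
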