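"""Reliable Components Analysis (RCA).

RCA finds electrode weightings w that maximise trial-to-trial covariance
of the evoked response: with Rxx the pooled within-trial spatial
covariance and Rxy the (symmetrized) across-trial cross-covariance at
identical time points, the components solve the generalized eigenproblem

    Rxy w = lambda Rxx w.

Eigenvalues order components by reliability; the ratio of an eigenvalue
to the sum of positive eigenvalues is its share of the total
trial-to-trial reliability.  Because the backward weights are not
interpretable as scalp maps, the forward-model projection
``A = Rxx W (W' Rxx W)^-1`` restores topographies in µV per unit
component.

The eigenproblem is solved inside a principal subspace of Rxx (PCA
truncation retaining, by default, the rank covering 99.9% of the trace)
to regularize against rank deficiency introduced by average referencing
and channel interpolation.

Covariances pool across participants by summing numerators and
pairwise-complete sample counts per participant, so missing samples are
handled exactly and trial pairs never cross participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.linalg

from .epochs import EpochSet


@dataclass
class CovariancePair:
    rxx: np.ndarray          # (C, C) pooled within-trial covariance
    rxy: np.ndarray          # (C, C) symmetrized across-trial cross-covariance
    n_within: np.ndarray     # effective sample counts behind rxx
    n_across: np.ndarray     # effective pair counts behind rxy

    def __post_init__(self) -> None:
        if not np.allclose(self.rxx, self.rxx.T, atol=1e-10):
            raise ValueError("rxx must be symmetric")
        if not np.allclose(self.rxy, self.rxy.T, atol=1e-10):
            raise ValueError("rxy must be symmetric")


@dataclass
class SpatialFilterSet:
    weights: np.ndarray               # (C, K) backward spatial filters
    forward: np.ndarray               # (C, K) forward-model topographies, µV
    eigenvalues: np.ndarray           # full descending spectrum
    reliability_fraction: np.ndarray  # per retained component
    regularization_rank: int
    channels: np.ndarray = None
    fit_window_ms: tuple = None
    locking: str = "stimulus"

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("weights", data=self.weights)
            f.create_dataset("forward", data=self.forward)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.create_dataset("reliability_fraction", data=self.reliability_fraction)
            if self.channels is not None:
                f.create_dataset("channels", data=np.asarray(self.channels))
            f.attrs["regularization_rank"] = self.regularization_rank
            f.attrs["locking"] = self.locking
            if self.fit_window_ms is not None:
                f.attrs["fit_window_ms"] = list(self.fit_window_ms)

    @classmethod
    def from_hdf5(cls, path) -> "SpatialFilterSet":
        with h5py.File(path, "r") as f:
            return cls(
                weights=f["weights"][()],
                forward=f["forward"][()],
                eigenvalues=f["eigenvalues"][()],
                reliability_fraction=f["reliability_fraction"][()],
                regularization_rank=int(f.attrs["regularization_rank"]),
                channels=f["channels"][()] if "channels" in f else None,
                fit_window_ms=tuple(f.attrs["fit_window_ms"]) if "fit_window_ms" in f.attrs else None,
                locking=str(f.attrs["locking"]),
            )


def compute_covariances(
    epochs: EpochSet | list[EpochSet],
    window_ms: tuple[float, float] | None = None,
) -> CovariancePair:
    """Pooled within- and across-trial covariances over a time window.

    ``epochs`` may be one :class:`EpochSet` or a list (one per
    participant); trial pairs are formed within each set only.  Each
    trial/channel is demeaned over its valid in-window samples.  Missing
    samples are excluded with pairwise-complete counts.
    """
    sets = epochs if isinstance(epochs, list) else [epochs]
    if not sets:
        raise ValueError("no epoch sets given")
    n_ch = sets[0].n_channels

    num_xx = np.zeros((n_ch, n_ch))
    cnt_xx = np.zeros((n_ch, n_ch))
    num_xy = np.zeros((n_ch, n_ch))
    cnt_xy = np.zeros((n_ch, n_ch))

    for es in sets:
        w = es.window(*window_ms) if window_ms is not None else es
        if w.n_trials < 2:
            raise ValueError("need at least 2 trials per participant")
        valid = w.valid()
        m = valid.astype(float)
        n_valid = m.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(valid, w.data, 0.0).sum(axis=2) / np.maximum(n_valid, 1)
        y = np.where(valid, w.data - mean[:, :, None], 0.0)

        yy = np.einsum("tcs,tds->cd", y, y)
        mm = np.einsum("tcs,tds->cd", m, m)
        s_y = y.sum(axis=0)   # (C, S)
        s_m = m.sum(axis=0)
        num_xx += yy
        cnt_xx += mm
        num_xy += s_y @ s_y.T - yy
        cnt_xy += s_m @ s_m.T - mm

    if (cnt_xx == 0).any() or (cnt_xy == 0).any():
        raise ValueError("some channel pairs have no overlapping valid samples")
    rxx = num_xx / cnt_xx
    rxy = num_xy / cnt_xy
    rxx = (rxx + rxx.T) / 2.0
    rxy = (rxy + rxy.T) / 2.0
    return CovariancePair(rxx=rxx, rxy=rxy, n_within=cnt_xx, n_across=cnt_xy)


def fit_rca(
    cov: CovariancePair,
    n_components: int = 2,
    regularization_rank: int | None = None,
    trace_fraction: float = 0.999,
    fit_window_ms: tuple | None = None,
    locking: str = "stimulus",
) -> SpatialFilterSet:
    """Solve the generalized eigenproblem in a principal subspace of Rxx.

    ``regularization_rank`` fixes the subspace dimension; by default the
    smallest rank whose eigenvalues cover ``trace_fraction`` of the Rxx
    trace is used.  Returns the top ``n_components`` filters, eigenvalues
    of the whole retained spectrum, and forward-model projections with
    the sign convention that each component's largest-|A| electrode is
    positive.
    """
    evals, evecs = np.linalg.eigh(cov.rxx)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals[0], 0) * 1e-12
    if regularization_rank is None:
        csum = np.cumsum(np.clip(evals, 0, None))
        rank = int(np.searchsorted(csum, trace_fraction * csum[-1]) + 1)
        rank = min(rank, int(pos.sum()))
    else:
        rank = int(regularization_rank)
        if rank > pos.sum():
            raise ValueError("requested regularization rank exceeds rank(Rxx)")
    if n_components > rank:
        raise ValueError("n_components exceeds the regularization rank")

    u = evecs[:, :rank]
    rxx_p = u.T @ cov.rxx @ u
    rxy_p = u.T @ cov.rxy @ u
    lam, v = scipy.linalg.eigh(rxy_p, rxx_p)
    lam, v = lam[::-1], v[:, ::-1]

    w = u @ v[:, :n_components]
    a = forward_model(w, cov.rxx)
    for k in range(n_components):
        j = int(np.argmax(np.abs(a[:, k])))
        if a[j, k] < 0:
            a[:, k] *= -1.0
            w[:, k] *= -1.0

    pos_lam = np.clip(lam, 0, None)
    total = pos_lam.sum()
    if total <= 0:
        raise ValueError("no positive reliability in the spectrum")
    return SpatialFilterSet(
        weights=w, forward=a, eigenvalues=lam,
        reliability_fraction=pos_lam[:n_components] / total,
        regularization_rank=rank, fit_window_ms=fit_window_ms, locking=locking,
    )


def forward_model(weights: np.ndarray, rxx: np.ndarray) -> np.ndarray:
    """Forward-model projection ``A = Rxx W (W' Rxx W)^-1`` (µV units)."""
    g = weights.T @ rxx @ weights
    try:
        inv = np.linalg.inv(g)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("W' Rxx W is singular") from e
    return rxx @ weights @ inv


def project(
    epochs: EpochSet, weights: np.ndarray, renormalize: bool = True
) -> EpochSet:
    """Project channel epochs through spatial filters.

    Returns a component :class:`EpochSet` of shape trials x K x samples.
    Where channels are missing, the weighted sum runs over available
    channels and is rescaled by the ratio of total to available absolute
    weight (``renormalize=False`` masks any sample with a missing
    channel instead).  Samples with no available channels stay missing.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != epochs.n_channels:
        raise ValueError("weight/channel dimension mismatch")
    valid = epochs.valid()
    y = np.einsum("ck,tcs->tks", w, np.where(valid, epochs.data, 0.0))
    absw = np.abs(w)
    avail = np.einsum("ck,tcs->tks", absw, valid.astype(float))
    total = absw.sum(axis=0)[None, :, None]
    if renormalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(avail > 0, y * total / np.where(avail > 0, avail, 1.0), np.nan)
        out_mask = ~(avail > 0)
    else:
        out_mask = avail < total - 1e-12
        y = np.where(out_mask, np.nan, y)
    trials = epochs.trials.copy()
    return EpochSet(
        data=y, mask=out_mask, time_ms=epochs.time_ms.copy(),
        channels=np.arange(1, w.shape[1] + 1), trials=trials,
        sfreq=epochs.sfreq, reference=epochs.reference, locking=epochs.locking,
    )


def reliability_explained(eigenvalues: np.ndarray, components) -> float:
    """Fraction of total trial-to-trial reliability carried by the given
    components (0-based indices into the descending spectrum).

    Negative eigenvalues contribute zero to both numerator and total.
    """
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are non-positive")
    idx = np.asarray(list(components), dtype=int)
    return float(lam[idx].sum() / total)
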