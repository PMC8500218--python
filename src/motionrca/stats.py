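"""Split-plot ANOVA, bootstrapped mass-univariate cluster statistics,
planned contrasts, correlations and the behavioural block score.

The centrepiece is the cluster-corrected mass-univariate test: at every
timepoint a two-way split-plot ANOVA (difficulty as the repeated-measures
factor, group as the between-participants factor) yields an F series per
effect.  The family-wise error rate across timepoints is controlled with
a max-cluster-sum bootstrap: the data are centered within each group x
condition cell, participants are resampled with replacement (within
group, preserving group sizes), and each of ``n_boot`` draws contributes
the maximum sum of F values over contiguous pointwise-significant
(p < .05) runs.  The (1 - alpha) quantile of these maxima is the cluster
threshold; observed clusters whose F sum strictly exceeds it are
significant.

With two within-participant levels the split-plot ANOVA has exact closed
forms on per-participant condition means m_i and differences d_i:

* group:        one-way ANOVA on m_i (between-subjects error),
* condition:    test of the unweighted mean of group-wise d means
                (the Type III hypothesis under unbalanced groups),
* interaction:  one-way ANOVA on d_i,

the last two sharing the condition-by-subjects error term.  These forms
vectorize over timepoints and bootstrap draws.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

EFFECTS = ("group", "condition", "interaction")


@dataclass
class MassUnivariateInput:
    """Per-participant waveforms: participants x 2 conditions x timepoints."""

    data: np.ndarray
    groups: np.ndarray               # (N,) labels
    time_ms: np.ndarray
    condition_names: tuple = ("easy", "difficult")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.groups = np.asarray(self.groups)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("data must be participants x 2 conditions x timepoints")
        if len(self.groups) != self.data.shape[0]:
            raise ValueError("group labels length mismatch")
        if len(self.time_ms) != self.data.shape[2]:
            raise ValueError("time axis length mismatch")
        if not np.isfinite(self.data).all():
            raise ValueError("waveform matrix contains non-finite values")

    @property
    def group_names(self) -> list:
        seen: list = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen


# ------------------------------------------------------------------ engine

def _group_structure(groups: np.ndarray):
    names: list = []
    for g in groups:
        if g not in names:
            names.append(g)
    gidx = np.array([names.index(g) for g in groups])
    n_g = np.bincount(gidx, minlength=len(names)).astype(float)
    onehot = np.zeros((len(names), len(groups)))
    onehot[gidx, np.arange(len(groups))] = 1.0
    return names, gidx, n_g, onehot


def _split_plot_f(data: np.ndarray, gidx: np.ndarray, n_g: np.ndarray,
                  onehot: np.ndarray) -> dict:
    """Vectorized split-plot F series.

    ``data`` has shape (..., N, 2, T); returns per effect a dict with
    the F array of shape (..., T), degrees of freedom, and the sums of
    squares needed for partial eta squared.
    """
    n_groups = len(n_g)
    n = float(data.shape[-3])
    m = data.mean(axis=-2)                       # (..., N, T)
    d = data[..., 1, :] - data[..., 0, :]        # (..., N, T)

    mg = np.einsum("gn,...nt->...gt", onehot, m) / n_g[:, None]
    dg = np.einsum("gn,...nt->...gt", onehot, d) / n_g[:, None]
    grand_m = m.mean(axis=-2)                    # weighted grand mean
    grand_d = d.mean(axis=-2)

    df_between = n_groups - 1
    df_err = int(n) - n_groups
    if df_err <= 0:
        raise ValueError("each group needs at least 2 participants")

    # between-participants (group) effect, subjects-within-groups error
    mg_per = mg[..., gidx, :]   # group means broadcast back to participants
    dg_per = dg[..., gidx, :]
    ss_b = np.einsum("g,...gt->...t", n_g, (mg - grand_m[..., None, :]) ** 2)
    ss_w = ((m - mg_per) ** 2).sum(axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_group = (ss_b / df_between) / (ss_w / df_err)

    # condition x subjects-within-groups error (difference-score scale)
    ss_e = ((d - dg_per) ** 2).sum(axis=-2)
    sigma2 = ss_e / df_err

    # condition main effect: Type III (unweighted group means) hypothesis
    du = dg.mean(axis=-2)
    c_coef = (1.0 / n_groups ** 2) * np.sum(1.0 / n_g)
    ss_c = du ** 2 / c_coef
    with np.errstate(invalid="ignore", divide="ignore"):
        f_cond = ss_c / sigma2

    # group x condition interaction
    ss_i = np.einsum("g,...gt->...t", n_g, (dg - grand_d[..., None, :]) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_int = (ss_i / df_between) / sigma2

    zero = lambda a: np.where(np.isfinite(a), a, 0.0)
    return {
        "group": {"f": zero(f_group), "df": (df_between, df_err), "ss": (ss_b, ss_w)},
        "condition": {"f": zero(f_cond), "df": (1, df_err), "ss": (ss_c, ss_e)},
        "interaction": {"f": zero(f_int), "df": (df_between, df_err), "ss": (ss_i, ss_e)},
    }


def split_plot_anova(data: np.ndarray, groups) -> pd.DataFrame:
    """Two-way split-plot ANOVA table for a participants x 2 matrix.

    Returns a table with F, degrees of freedom, p and partial eta
    squared for the group, condition and interaction effects.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("data must be participants x 2 conditions")
    groups = np.asarray(groups)
    _, gidx, n_g, onehot = _group_structure(groups)
    if (n_g < 2).any():
        raise ValueError("each group needs at least 2 participants")
    res = _split_plot_f(data[:, :, None], gidx, n_g, onehot)
    rows = []
    for eff in EFFECTS:
        r = res[eff]
        f = float(r["f"][0])
        df1, df2 = r["df"]
        ss_eff, ss_err = float(r["ss"][0][0]), float(r["ss"][1][0])
        rows.append({
            "effect": eff, "F": f, "df_num": df1, "df_den": df2,
            "p": float(sps.f.sf(f, df1, df2)),
            "eta_p2": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
        })
    return pd.DataFrame(rows)


def center_by_cell(data: np.ndarray, groups) -> np.ndarray:
    """Subtract each group x condition cell mean at every timepoint."""
    data = np.asarray(data, dtype=float)
    out = data.copy()
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        out[sel] -= data[sel].mean(axis=0, keepdims=True)
    return out


# ------------------------------------------------------------- clustering

def _cluster_runs(sig: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, end) inclusive sample indices."""
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _max_cluster_sums(f: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """Row-wise maximum cluster sum; 0 when a row has no significant run."""
    f2 = np.where(sig, f, 0.0)
    out = np.zeros(f.shape[0])
    for b in range(f.shape[0]):
        best = 0.0
        for s, e in _cluster_runs(sig[b]):
            best = max(best, float(f2[b, s:e + 1].sum()))
        out[b] = best
    return out


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    cluster_sum: float
    significant: bool
    mean_difference_uv: float | None = None


@dataclass
class EffectClusterResult:
    effect: str
    f: np.ndarray
    p: np.ndarray
    df: tuple
    clusters: list
    threshold: float
    max_sums: np.ndarray

    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.significant]


@dataclass
class ClusterTestResult:
    effects: dict
    time_ms: np.ndarray
    n_boot: int
    pointwise_alpha: float
    cluster_alpha: float
    seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "n_boot": self.n_boot, "pointwise_alpha": self.pointwise_alpha,
            "cluster_alpha": self.cluster_alpha, "seed": self.seed,
            "time_ms": self.time_ms.tolist(),
            "effects": {
                name: {
                    "f": e.f.tolist(), "p": e.p.tolist(), "df": list(e.df),
                    "threshold": e.threshold,
                    "clusters": [asdict(c) for c in e.clusters],
                }
                for name, e in self.effects.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def bootstrap_cluster_test(
    inp: MassUnivariateInput,
    n_boot: int = 2000,
    pointwise_alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | None = 0,
    within_group: bool = True,
    chunk: int = 200,
) -> ClusterTestResult:
    """Mass-univariate split-plot ANOVA with max-cluster-sum correction.

    Bootstrap draws resample participants' cell-centered data with
    replacement; ``within_group=True`` (default) resamples within each
    group, preserving the between-participants design and group sizes.
    An iteration with no pointwise-significant timepoint contributes a
    maximum cluster sum of 0.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable cluster threshold")
    if inp.data.shape[2] < 2:
        raise ValueError("need at least 2 timepoints")
    names, gidx, n_g, onehot = _group_structure(inp.groups)
    if (n_g < 2).any():
        raise ValueError("each group needs at least 2 participants")
    rng = np.random.default_rng(seed)
    n = inp.data.shape[0]

    centered = center_by_cell(inp.data, inp.groups)
    crit = {
        eff: sps.f.isf(pointwise_alpha, *df)
        for eff, df in (("group", (len(n_g) - 1, n - len(n_g))),
                        ("condition", (1, n - len(n_g))),
                        ("interaction", (len(n_g) - 1, n - len(n_g))))
    }

    max_sums = {eff: np.empty(n_boot) for eff in EFFECTS}
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = np.empty((b, n), dtype=int)
        if within_group:
            for gi in range(len(n_g)):
                members = np.flatnonzero(gidx == gi)
                idx[:, members] = rng.choice(members, size=(b, members.size))
        else:
            idx[:] = rng.integers(0, n, size=(b, n))
        boot = centered[idx]                      # (b, N, 2, T)
        res = _split_plot_f(boot, gidx, n_g, onehot)
        for eff in EFFECTS:
            f = res[eff]["f"]
            max_sums[eff][done:done + b] = _max_cluster_sums(f, f > crit[eff])
        done += b

    obs = _split_plot_f(inp.data[None], gidx, n_g, onehot)
    effects = {}
    for eff in EFFECTS:
        f = obs[eff]["f"][0]
        df = obs[eff]["df"]
        p = sps.f.sf(f, *df)
        thr = float(np.quantile(max_sums[eff], 1.0 - cluster_alpha))
        clusters = []
        for s, e in _cluster_runs(f > crit[eff]):
            csum = float(f[s:e + 1].sum())
            clusters.append(Cluster(
                start_ms=float(inp.time_ms[s]), end_ms=float(inp.time_ms[e]),
                cluster_sum=csum, significant=bool(csum > thr),
            ))
        effects[eff] = EffectClusterResult(
            effect=eff, f=f, p=p, df=df, clusters=clusters,
            threshold=thr, max_sums=max_sums[eff],
        )
    return ClusterTestResult(
        effects=effects, time_ms=inp.time_ms.copy(), n_boot=n_boot,
        pointwise_alpha=pointwise_alpha, cluster_alpha=cluster_alpha, seed=seed,
    )


def followup_pairwise_cluster(
    inp: MassUnivariateInput,
    groups_pair: tuple,
    window_ms: tuple[float, float],
    n_boot: int = 2000,
    seed: int | None = 0,
    reference: str = "TD",
    **kwargs,
) -> ClusterTestResult:
    """Two-group follow-up cluster analysis restricted to a time window.

    Runs the same bootstrap-cluster machinery on the subset of
    participants belonging to ``groups_pair`` and the samples inside the
    omnibus cluster's window.  Significant clusters carry the direction
    of the difference (mean of the non-reference group minus the
    reference group over the cluster).
    """
    sel_t = (inp.time_ms >= window_ms[0]) & (inp.time_ms <= window_ms[1])
    if not sel_t.any():
        raise ValueError("empty follow-up window")
    sel_p = np.isin(inp.groups, list(groups_pair))
    sub = MassUnivariateInput(
        data=inp.data[np.ix_(sel_p, [0, 1], np.flatnonzero(sel_t))],
        groups=inp.groups[sel_p], time_ms=inp.time_ms[sel_t],
        condition_names=inp.condition_names,
    )
    result = bootstrap_cluster_test(sub, n_boot=n_boot, seed=seed, **kwargs)
    other = [g for g in groups_pair if g != reference]
    if other:
        diff = (
            sub.data[sub.groups == other[0]].mean(axis=(0, 1))
            - sub.data[sub.groups == reference].mean(axis=(0, 1))
        )
        for eff in result.effects.values():
            for c in eff.clusters:
                m = (sub.time_ms >= c.start_ms) & (sub.time_ms <= c.end_ms)
                c.mean_difference_uv = float(diff[m].mean())
    return result


# ----------------------------------------------------- contrasts and misc

def planned_simple_contrasts(
    values: np.ndarray, groups, reference: str = "TD"
) -> dict:
    """Each non-reference group vs the reference, tested against the
    pooled subjects-within-groups error term.

    ``values`` are per-participant condition-averaged scores.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names, gidx, n_g, _ = _group_structure(groups)
    if reference not in names:
        raise ValueError(f"reference group {reference!r} absent")
    means = np.array([values[gidx == i].mean() for i in range(len(names))])
    ss_w = sum(((values[gidx == i] - means[i]) ** 2).sum() for i in range(len(names)))
    df = len(values) - len(names)
    ms_w = ss_w / df
    ref = names.index(reference)
    out = {}
    for i, name in enumerate(names):
        if name == reference:
            continue
        se = math.sqrt(ms_w * (1.0 / n_g[i] + 1.0 / n_g[ref]))
        t = (means[i] - means[ref]) / se if se > 0 else 0.0
        out[name] = {
            "estimate": float(means[i] - means[ref]),
            "t": float(t), "df": int(df),
            "p": float(2 * sps.t.sf(abs(t), df)),
        }
    return out


def pearson_correlations(x: np.ndarray, measures: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (two-sided p) between ``x`` and each measure column,
    pairwise-complete over missing scores."""
    x = np.asarray(x, dtype=float)
    rows = []
    for col in measures.columns:
        y = measures[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 paired observations for {col!r}")
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            raise ValueError(f"zero variance in correlation with {col!r}")
        r, p = sps.pearsonr(x[ok], y[ok])
        rows.append({"measure": col, "n": int(ok.sum()), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def block_score(median_rt_s: float, n_correct: int) -> int:
    """End-of-block feedback score: (1 / median RT) * correct * 2,
    rounded to the nearest integer (half away from zero)."""
    if median_rt_s <= 0:
        raise ValueError("median RT must be positive")
    v = (1.0 / median_rt_s) * n_correct * 2.0
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))
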