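"""End-to-end orchestration: synth -> preprocess -> RCA -> waveforms -> stats.

A :class:`PipelineConfig` fully determines a run: a master seed spawns a
deterministic seed for every stochastic stage (per task, group and
participant), so a run is a pure function of its config.  Normative
spatial filters are fitted on the typically developing (TD) group only
and every group's data are projected through them.

Stage artifacts (behaviour tables, spatial filters, waveforms, cluster
results, preprocessing reports) are persisted under ``out_dir`` so each
stage can be re-run and inspected independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, rca, stats, waveforms
from .montage import Montage, hydrocel_128
from .synth import (
    BehaviorModel,
    default_ground_truth,
    make_session_plan,
    simulate_behavior,
    simulate_eeg,
)

GROUPS = ("TD", "autistic", "dyslexic")


@dataclass
class PipelineConfig:
    out_dir: str = "motionrca_run"
    tasks: tuple = ("coherence", "integration")
    group_sizes: dict = field(default_factory=lambda: {"TD": 57, "autistic": 29, "dyslexic": 44})
    master_seed: int = 0
    n_per_level: int = 72
    n_catch: int = 8
    blocks: int = 4
    sim_window_ms: tuple = (-2000.0, 1000.0)
    fit_window_ms: tuple = (-100.0, 600.0)
    char_window_ms: tuple = (-100.0, 800.0)
    response_window_ms: tuple = (-600.0, 200.0)
    n_components: int = 2
    regularization_rank: int | None = None   # None: 99.9%-trace truncation
    n_boot: int = 2000
    pointwise_alpha: float = 0.05
    cluster_alpha: float = 0.05
    noise_sd_uv: float = 8.0
    gain_jitter_sd: tuple = (0.25, 0.5)
    bad_channel_prob: float = 0.01
    transient_prob: float = 1e-5
    #: {(group, component_name): (t0_ms, t1_ms, delta_uv)} per task
    group_effects: dict = field(default_factory=dict)
    response_locked: bool = False
    reference_group: str = "TD"


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of invariant violations (empty when valid)."""
    v = []
    if config.master_seed is None:
        v.append("master_seed: every stochastic stage needs an explicit seed")
    for name in ("pointwise_alpha", "cluster_alpha"):
        a = getattr(config, name)
        if not 0.0 < a < 1.0:
            v.append(f"{name}: must lie in (0, 1), got {a}")
    for g, n in config.group_sizes.items():
        if n < 2:
            v.append(f"group_sizes[{g!r}]: need at least 2 participants")
    if config.reference_group not in config.group_sizes:
        v.append("reference_group: absent from group_sizes")
    for t in config.tasks:
        if t not in ("coherence", "integration"):
            v.append(f"tasks: unknown task {t!r}")
    if config.n_per_level % 2 or config.n_catch % 2:
        v.append("n_per_level/n_catch: must be even for direction balance")
    if (2 * config.n_per_level + config.n_catch) % config.blocks:
        v.append("blocks: total trial count must divide evenly into blocks")
    if config.n_boot < 100:
        v.append("n_boot: fewer than 100 bootstrap iterations")
    f0, f1 = config.fit_window_ms
    s0, s1 = config.sim_window_ms
    if not (s0 <= f0 < f1 <= s1):
        v.append("fit_window_ms: must lie within sim_window_ms")
    return v


def stage_seed(master_seed: int, *keys) -> int:
    """Deterministic per-stage seed below 2**31."""
    ent = [int(master_seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(ent).generate_state(1)[0] % (2 ** 31))


def _cluster_summary(result: stats.ClusterTestResult) -> dict:
    return {
        eff: {
            "threshold": e.threshold,
            "clusters": [
                {"start_ms": c.start_ms, "end_ms": c.end_ms,
                 "cluster_sum": c.cluster_sum, "significant": c.significant,
                 "mean_difference_uv": c.mean_difference_uv}
                for c in e.clusters
            ],
        }
        for eff, e in result.effects.items()
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class RunReport:
    config: dict
    tasks: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonable({"config": self.config, "tasks": self.tasks}),
                      fh, indent=2, default=str)


def run_full_pipeline(config: PipelineConfig, montage: Montage | None = None) -> RunReport:
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    montage = montage or hydrocel_128()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))

    for task in config.tasks:
        task_dir = out / task
        task_dir.mkdir(exist_ok=True)
        gt = default_ground_truth(
            montage,
            noise_sd_uv=config.noise_sd_uv,
            gain_jitter_sd=config.gain_jitter_sd,
            bad_channel_prob=config.bad_channel_prob,
            transient_prob=config.transient_prob,
            group_effects=dict(config.group_effects.get(task, {})),
        )

        cleaned: dict[str, list] = {}
        behaviour_rows = []
        preproc_summaries = []
        for group, n in config.group_sizes.items():
            cleaned[group] = []
            for p in range(n):
                pid = f"{group}_{p:03d}"
                plan = make_session_plan(
                    task, seed=stage_seed(config.master_seed, task, pid, "plan"),
                    n_per_level=config.n_per_level, n_catch=config.n_catch,
                    blocks=config.blocks,
                )
                plan = simulate_behavior(
                    plan, BehaviorModel.for_task(task),
                    seed=stage_seed(config.master_seed, task, pid, "behaviour"),
                )
                epochs, _truth = simulate_eeg(
                    plan, gt, seed=stage_seed(config.master_seed, task, pid, "eeg"),
                    group=group, participant=pid, window_ms=config.sim_window_ms,
                )
                clean, prep = preprocess.preprocess_epochs(epochs, montage)
                cleaned[group].append(clean)
                preproc_summaries.append({
                    "participant": pid,
                    "percent_electrodes_replaced": prep.percent_electrodes_replaced,
                    "percent_trial_channels_removed": prep.percent_trial_channels_removed,
                    "percent_trials_removed": prep.percent_trials_removed,
                })
                for diff in ("easy", "difficult"):
                    sub = [t for t in plan.trials if t.difficulty == diff]
                    rts = [t.rt_ms for t in sub if t.correct]
                    behaviour_rows.append({
                        "participant": pid, "group": group, "difficulty": diff,
                        "accuracy": float(np.mean([bool(t.correct) for t in sub])),
                        "median_rt_ms": float(np.median(rts)) if rts else np.nan,
                    })

        behaviour = pd.DataFrame(behaviour_rows)
        behaviour.to_csv(task_dir / "behaviour.csv", index=False)

        # --- RCA on the reference (TD) group; project everyone ---------
        cov = rca.compute_covariances(
            cleaned[config.reference_group], window_ms=config.fit_window_ms
        )
        filters = rca.fit_rca(
            cov, n_components=config.n_components,
            regularization_rank=config.regularization_rank,
            fit_window_ms=config.fit_window_ms,
        )
        filters.channels = montage.channels.copy()
        filters.to_hdf5(task_dir / "spatial_filters.h5")
        pd.DataFrame(
            {"channel": montage.channels,
             **{f"component_{k + 1}": filters.forward[:, k]
                for k in range(config.n_components)}}
        ).to_csv(task_dir / "topographies.csv", index=False)

        wave_list = []
        per_part: dict[str, dict] = {}
        for group, sets in cleaned.items():
            for es in sets:
                comp = rca.project(es.window(*config.char_window_ms), filters.weights)
                pid = es.trials["participant"].iloc[0]
                per_part[pid] = {"group": group}
                for k in range(1, config.n_components + 1):
                    for diff in ("easy", "difficult"):
                        w = waveforms.average_participant_waveform(
                            comp, component=k, selector={"difficulty": diff}
                        )
                        wave_list.append(w)
                        per_part[pid][(k, diff)] = w
        waveforms.waveforms_to_frame(wave_list).to_csv(
            task_dir / "component_waveforms.csv", index=False
        )

        # --- mass-univariate cluster statistics per component ----------
        pids = sorted(per_part)
        groups_arr = np.array([per_part[p]["group"] for p in pids])
        time_axis = wave_list[0].time_ms
        task_report: dict = {
            "preprocessing": preproc_summaries,
            "reliability_fraction": filters.reliability_fraction.tolist(),
            "reliability_first_two": rca.reliability_explained(
                filters.eigenvalues, range(min(2, config.n_components))
            ),
            "components": {},
        }
        seed_ct = stage_seed(config.master_seed, task, "cluster")
        for k in range(1, config.n_components + 1):
            mat = np.stack([
                np.stack([per_part[p][(k, "easy")].amplitude_uv,
                          per_part[p][(k, "difficult")].amplitude_uv])
                for p in pids
            ])
            inp = stats.MassUnivariateInput(data=mat, groups=groups_arr, time_ms=time_axis)
            result = stats.bootstrap_cluster_test(
                inp, n_boot=config.n_boot, pointwise_alpha=config.pointwise_alpha,
                cluster_alpha=config.cluster_alpha, seed=seed_ct + k,
            )
            result.to_json(task_dir / f"clusters_component{k}.json")
            comp_report = {"omnibus": _cluster_summary(result), "followups": {}}
            for c in result.effects["group"].significant_clusters():
                for other in config.group_sizes:
                    if other == config.reference_group:
                        continue
                    fu = stats.followup_pairwise_cluster(
                        inp, (config.reference_group, other),
                        (c.start_ms, c.end_ms), n_boot=config.n_boot,
                        seed=seed_ct + 100 + k, reference=config.reference_group,
                    )
                    comp_report["followups"][f"{other}_{c.start_ms:.0f}-{c.end_ms:.0f}ms"] = (
                        _cluster_summary(fu)
                    )
            task_report["components"][f"component_{k}"] = comp_report

        # --- N2-like peak measures and correlations ---------------------
        occ_k = waveforms.occipital_component(filters.forward, montage)
        task_report["occipital_component"] = occ_k
        peak_rows = []
        for p in pids:
            amps = []
            for diff in ("easy", "difficult"):
                pk = waveforms.extract_peak(per_part[p][(occ_k, diff)])
                amps.append(pk.amplitude_uv)
                peak_rows.append({
                    "participant": p, "group": per_part[p]["group"], "difficulty": diff,
                    "amplitude_uv": pk.amplitude_uv, "latency_ms": pk.latency_ms,
                })
            peak_rows.append({
                "participant": p, "group": per_part[p]["group"], "difficulty": "mean",
                "amplitude_uv": float(np.mean(amps)), "latency_ms": np.nan,
            })
        peaks = pd.DataFrame(peak_rows)
        peaks.to_csv(task_dir / "n2_peaks.csv", index=False)

        mean_peaks = peaks[peaks.difficulty == "mean"].set_index("participant")
        beh_wide = behaviour.pivot_table(
            index="participant", columns="difficulty",
            values=["accuracy", "median_rt_ms"],
        )
        meas = pd.DataFrame({
            "accuracy": beh_wide["accuracy"].mean(axis=1),
            "median_rt_ms": beh_wide["median_rt_ms"].mean(axis=1),
        }).loc[pids]
        corr = stats.pearson_correlations(
            mean_peaks.loc[pids, "amplitude_uv"].to_numpy(), meas
        )
        corr.to_csv(task_dir / "peak_correlations.csv", index=False)
        task_report["peak_correlations"] = corr.to_dict(orient="records")

        # --- behavioural split-plot ANOVAs ------------------------------
        task_report["behaviour"] = {}
        for measure in ("accuracy", "median_rt_ms"):
            wide = behaviour.pivot(index="participant", columns="difficulty",
                                   values=measure).loc[pids]
            mat = wide[["easy", "difficult"]].to_numpy()
            ok = np.isfinite(mat).all(axis=1)
            table = stats.split_plot_anova(mat[ok], groups_arr[ok])
            contrasts = stats.planned_simple_contrasts(
                mat[ok].mean(axis=1), groups_arr[ok], reference=config.reference_group
            )
            task_report["behaviour"][measure] = {
                "anova": table.to_dict(orient="records"),
                "planned_contrasts": contrasts,
            }

        # --- response-locked analysis (optional) ------------------------
        if config.response_locked:
            rl_sets = {g: [waveforms.response_locked_epochs(es, config.response_window_ms)
                           for es in sets] for g, sets in cleaned.items()}
            cov_rl = rca.compute_covariances(rl_sets[config.reference_group])
            filt_rl = rca.fit_rca(cov_rl, n_components=config.n_components,
                                  regularization_rank=config.regularization_rank,
                                  locking="response")
            filt_rl.to_hdf5(task_dir / "spatial_filters_response.h5")
            rl_mat, rl_groups = [], []
            for g, sets in rl_sets.items():
                for es in sets:
                    comp = rca.project(es, filt_rl.weights)
                    rows = []
                    for diff in ("easy", "difficult"):
                        w = waveforms.average_participant_waveform(
                            comp, component=1, selector={"difficulty": diff})
                        rows.append(np.nan_to_num(w.amplitude_uv))
                    rl_mat.append(np.stack(rows))
                    rl_groups.append(g)
            inp_rl = stats.MassUnivariateInput(
                data=np.stack(rl_mat), groups=np.array(rl_groups),
                time_ms=comp.time_ms,
            )
            res_rl = stats.bootstrap_cluster_test(
                inp_rl, n_boot=config.n_boot, seed=seed_ct + 500)
            res_rl.to_json(task_dir / "clusters_response_component1.json")
            task_report["response_locked_component_1"] = _cluster_summary(res_rl)

        report.tasks[task] = task_report

    report.to_json(out / "run_report.json")
    return report
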