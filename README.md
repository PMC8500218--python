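# motionrca

A tested Python pipeline for component-based analysis of global-motion
evoked potentials, aimed at researchers studying visual motion
processing with high-density EEG — including cross-group comparisons
(e.g. typically developing vs autistic vs dyslexic children) where the
original participant data are restricted-access and every analysis
stage must be verifiable on synthetic data with known ground truth.

The package covers the full chain:

* **synth** — random-dot-kinematogram session plans (motion coherence
  and direction integration tasks: 72 trials per difficulty level, 8
  catch trials, 4 blocks of 38), dot kinematics, simulated behaviour,
  and 128-channel synthetic EEG built as a linear mixture of an
  occipital motion-onset component (P1-like, N2-like at 160 ms, P2-like
  deflections) and a centro-parietal decision-like ramp, plus realistic
  artifacts (EOG leakage, bad channels, transients);
* **preprocess** — 0.3–40 Hz zero-phase band-pass, median DC
  correction, bad-electrode interpolation, EOG regression, trial-wise
  channel masking, ≥4 SD transient substitution, trial rejection,
  average reference and pre-stimulus baseline;
* **rca** — Reliable Components Analysis;
* **waveforms** — per-participant/group component waveforms, N2-like
  peak scoring (minimum in 100–250 ms), the traditional 9-electrode
  occipital average, response-locked re-windowing;
* **stats** — mass-univariate split-plot ANOVA with bootstrapped
  max-cluster-sum family-wise error control, follow-up pairwise cluster
  analyses, planned contrasts, Pearson correlations;
* **cli / pipeline** — a `motionrca` command and `run_full_pipeline`
  orchestrating everything deterministically from one seeded config.

## The core method

RCA finds electrode weightings **w** that maximise the trial-to-trial
covariance of the evoked response.  With R<sub>xx</sub> the pooled
within-trial spatial covariance and R<sub>xy</sub> the symmetrized
across-trial cross-covariance at identical timepoints, components solve
the generalized eigenproblem

&nbsp;&nbsp;&nbsp;&nbsp;R<sub>xy</sub> **w** = λ R<sub>xx</sub> **w**,

solved in a principal subspace of R<sub>xx</sub> for regularization.
Eigenvalues rank components by reliability; forward models
**A** = R<sub>xx</sub> **W** (**W**ᵀR<sub>xx</sub>**W**)⁻¹ give
interpretable scalp topographies.  Weights are fitted on a normative
(reference) group and all groups' data are projected through them.
Group/condition effects on the component waveforms are tested at every
timepoint with a 2 (difficulty, within) × 3 (group, between) split-plot
ANOVA; family-wise error across timepoints is controlled by bootstrap:
cell-centered data are resampled with replacement within group, the
maximum sum of F values over contiguous pointwise-significant (p < .05)
runs is recorded per draw, and observed clusters are significant when
their F sum exceeds the 95th percentile of those maxima.

## Worked example

```python
import numpy as np
from motionrca.montage import hydrocel_128
from motionrca.synth import make_session_plan, make_component_recovery_data
from motionrca import rca, stats

montage = hydrocel_128()

# a full experimental session plan
plan = make_session_plan("coherence", seed=1)
print(plan.n_trials, plan.counts())

# recover two injected components (3:1 reliabilities, SNR 0.5)
epochs, true_topo = make_component_recovery_data(montage, seed=0)
filters = rca.fit_rca(rca.compute_covariances(epochs), n_components=2)
print(np.round(filters.eigenvalues[:4], 3), np.round(filters.reliability_fraction, 3))
for k in range(2):
    r = np.corrcoef(filters.forward[:, k], true_topo[:, k])[0, 1]
    print(f"component {k+1}: |corr| with true topography = {abs(r):.3f}")

# cluster-corrected mass-univariate ANOVA on an injected condition effect
rng = np.random.default_rng(0)
t = np.arange(50) * 10.0
data = rng.standard_normal((36, 2, 50))
data[:, 1, (t >= 200) & (t <= 300)] += 1.0
inp = stats.MassUnivariateInput(
    data=data, groups=np.array(["TD"]*12 + ["autistic"]*12 + ["dyslexic"]*12),
    time_ms=t)
res = stats.bootstrap_cluster_test(inp, n_boot=500, seed=0)
print([(c.start_ms, c.end_ms) for c in res.effects["condition"].clusters
       if c.significant])
```

prints

```
152 {'difficult': 72, 'easy': 72, 'catch': 8}
[0.702 0.358 0.024 0.022] [0.442 0.225]
component 1: |corr| with true topography = 0.994
component 2: |corr| with true topography = 1.000
[(200.0, 300.0)]
```

The session reproduces the full design (72 + 72 + 8 trials in 4 blocks
of 38).  The two leading generalized eigenvalues (0.702, 0.358) stand
far above the noise floor of the spectrum and carry 44% and 23% of the
total trial-to-trial reliability; both forward-model topographies match
the injected mixing columns almost perfectly.  The cluster test flags a
single significant difficulty cluster exactly over the 200–300 ms
window where the effect was injected, while the (null) group effect
produces none.

An end-to-end run from a JSON config:

```bash
motionrca run --config config.json --out results/ --seed 11
```

writes per-task behaviour tables, fitted spatial filters and
topographies, component waveforms, N2 peak tables, cluster-test JSONs
and a `run_report.json` tying them together.

## Documentation

`docs/methods.md` describes the generative model, the preprocessing
rules and their edge-case semantics, the RCA regularization, the
bootstrap cluster procedure, and what passing the synthetic benchmarks
does and does not demonstrate.
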