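# Methods

`motionrca` implements a component-based analysis of global-motion evoked
potentials: a synthetic random-dot-kinematogram (RDK) session and EEG
generator with known ground truth, an artifact-rejection chain,
Reliable Components Analysis (RCA) spatial filtering, component waveform
and peak measures, and a bootstrapped mass-univariate split-plot ANOVA
with max-cluster-sum family-wise error control.  This note documents the
models, the choices that were genuinely open, and what the synthetic
benchmarks do and do not establish.

## Experimental design emulated by the generator

Two tasks are modelled.  In the **motion coherence** task a fraction of
dots share the trial direction (easy 75%, difficult 30%, catch 100%); in
the **direction integration** task every dot direction is drawn from a
Gaussian around the trial direction (easy SD 30°, difficult SD 70°,
catch SD 0°).  A full session has 72 trials per non-catch difficulty
level (half leftward, half rightward) plus 8 catch trials, in 4 blocks
of 38.  Each trial has a fixation period (uniform 800–1000 ms), a
random-motion period (800–1000 ms) isolating direction-specific
responses from luminance onset, a stimulus period ending at the response
or after 2500 ms, and an offset period (200–400 ms).  Dot kinematics run
at 60 Hz with 400 ms limited lifetime (24 frames, starting lifetimes
randomized) and wrap-around at the 10°×10° field edge.  Whether the
coherent subset is re-drawn each frame ("different-dot" rule, the
default) or fixed, and whether integration directions are sampled at dot
birth (default) or each frame, are configuration options: the underlying
display algorithm is not uniquely determined by the task description,
and neither choice affects any downstream statistic tested here.

**Behaviour** is generated, not fitted: Bernoulli accuracy and
log-normal RTs per condition, truncated at the 2500 ms limit (truncation
= timeout, recorded as no response).  Defaults (coherence: accuracy
.92/.82, RT medians 0.9/1.25 s; integration: .93/.78, 0.95/1.2 s;
log-scale SD 0.35) were chosen once to echo the qualitative pattern the
downstream ANOVAs assume — slower and, in the integration task, less
accurate responding in the difficult condition — at child-plausible RT
scales.  The block feedback score is
`round((1 / median RT in s) * n_correct * 2)` with half-away-from-zero
rounding (the rounding direction at exact halves is a convention; the
formula's source does not specify it).

## Synthetic EEG model

Each trial is a linear mixture `x(t) = A (g ∘ s(t)) + noise + EOG +
artifacts` over the 128-channel HydroCel-style montage (idealized
GSN-HydroCel-128 coordinates bundled with mne, normalized to the unit
sphere; real digitized coordinates can be passed to `Montage` directly).
Two components are injected:

* **occipital** (Gaussian topography centred on Oz/E75): motion-onset
  morphology with a small negativity at 60 ms, P1-like positivity at
  100 ms (+4 µV), N2-like negativity at 160 ms (−5 µV) and a P2-like
  positivity at ~270 ms whose amplitude carries the difficulty effect
  (easy 3.5, difficult 2.3 µV);
* **centro-parietal** (centred on Pz/E62): an early auditory-cue bump
  and a logistic decision-like ramp peaking late (easy 6.0 µV at
  ~380 ms, difficult 5.0 µV at ~430 ms).

Trial-to-trial unreliability comes from per-component Gaussian amplitude
gains `g ~ N(1, σ)` with σ = 0.1 (centro-parietal) and 0.45 (occipital):
the reliability RCA measures along a component's direction is
`μ²/(μ²+σ²)` before noise, so unequal σ separates the spectrum.  Noise
is spatially correlated (squared-exponential kernel over chord
distances, length 0.5) and temporally smoothed; default per-channel SD
is 2.5 µV.  Because the injected topographies are unit-norm (so the
per-electrode signal is diluted roughly five-fold relative to the
printed component amplitudes), this default should be read as an
*effective* noise level chosen so that a full single-participant session
yields recoverable components, not as a literal scalp-EEG noise floor.
EOG leakage uses blink events (50 ms Gaussian pulses, 100–200 µV,
Poisson timing that may straddle the epoch edges so the expected blink
profile is stationary over the window) plus smooth drifts, mixed through
gain fields anchored at the montage's EOG role electrodes (HEOG:
125 − 128; VEOG: (8+25) − (126+127)).  Optional artifacts: whole-session
bad channels replaced by high-amplitude noise, and sparse transient
spikes (only at samples inside a trial's valid span, and not on bad
channels, which are already noise).

What the generator does **not** emulate: volume-conduction forward
physics, 1/f spectral shape, alpha rhythms, non-stationary artifacts
(sweat, movement), latency jitter of the evoked components, or any
dependence of the neural response on the actual dot kinematics.
Passing recovery tests therefore shows the pipeline's operations are
correct under the linear-mixture model the methods assume; they do not
certify performance on real paediatric EEG.

## Preprocessing chain

Stages run in a fixed order: 0.3–40 Hz zero-phase band-pass → epoching
and per-trial/channel median DC correction → bad-electrode detection and
neighbour interpolation → EOG regression → trial-wise channel masking →
transient substitution → trial rejection → flat-channel removal →
average reference → baseline to the last 100 ms of random motion.
Masking only ever grows the missing mask; interpolation is the single
declared stage that fills values.  Numerical choices where the procedure
was under-specified:

* the 97.5th absolute-amplitude percentile is computed per participant
  **pooled over all channels, trials and valid samples**, once, and the
  same threshold serves the session-level rule (≥15% offending samples
  flags a channel) and the trial-level rule (≥15% masks a
  trial-channel); note the trial-rejection rule is strict (*more than*
  15% of channels), unlike the two channel rules;
* transient statistics (mean/SD, ≥4 SD masks a sample) are per channel
  over the whole session, for stability at realistic trial counts;
* interpolation uses the 6 nearest non-flagged neighbours by 3-D
  distance, escalating past flagged ones;
* the filter is a 4th-order Butterworth applied with `sosfiltfilt`
  (masked samples zero-filled for filtering, then re-masked); the
  original acquisition filter's realization is unknown, so this is a
  documented, swappable stand-in;
* EOG regression is ordinary least squares of each channel on
  [HEOG, VEOG, 1] over its valid session samples.

## Reliable Components Analysis

With `Rxx` the pooled within-trial spatial covariance and `Rxy` the
symmetrized across-trial cross-covariance at identical timepoints
(ordered trial pairs i≠j, pairs formed within participant only, pooled
across participants by summing numerators and pairwise-complete counts),
RCA solves `Rxy w = λ Rxx w`.  The fit window is [−100, 600) ms around
stimulus onset; projection for characterization uses [−100, 800) ms, and
response-locked fits use [−600, 200) ms around the response (responded
trials only).  Both matrices are projected into the leading principal
subspace of `Rxx` before solving; the default retains 99.9% of the
trace, and the subspace rank is configurable.  At reduced problem sizes
the top spurious eigenvalue of the cross-trial estimator grows with the
subspace dimension relative to the number of trial pairs, so desk-scale
analyses in the tests and demos use rank 32; at full-study scale the
trace criterion is adequate.  Eigenvalues are reported as reliability
fractions `max(λ,0)/Σ max(λ,0)` — an eigenvalue-ratio accounting, which
is one of several possible definitions of "share of total reliability"
and is labelled as such.  Forward models `A = Rxx W (WᵀRxxW)⁻¹` restore
interpretable topographies; each component's sign is fixed so its
largest-|A| electrode is positive (cosmetic).  Projection through
missing channels renormalizes by the ratio of total to available
absolute weight (configurable to masking instead).

On synthetic sessions at reduced scale the occipital component is often
*more* reliable than the centro-parietal one, i.e. the eigenvalue
ordering can differ from the full study's.  Analyses that need "the
occipital component" therefore identify it by the forward-model
amplitude over the 9-electrode occipital ROI rather than by rank.

## Waveforms and peaks

Per-participant waveforms are trial averages of projected component time
courses (missing samples ignored); group summaries are across-participant
means with SEM.  The N2-like peak is the minimum between 100 and 250 ms,
endpoints inclusive (an open question in the procedure; inclusivity is
the safer convention for a sampled grid), ties broken to the earliest
sample, boundary extrema flagged.  For peak–behaviour correlations the
peak amplitude is the unweighted mean of the two per-condition peaks.
The traditional occipital measure averages electrodes 50, 58, 65, 70, 75
(Oz), 83, 90, 96, 101 and equals a spatial-filter projection with
uniform 1/9 weights.  Response-locked re-windowing aligns at the sample
nearest the recorded RT (RTs need not fall on the 2 ms grid) and pads
out-of-epoch samples with missing values.

## Statistics

The mass-univariate engine runs a two-way split-plot ANOVA (2 within ×
2–3 between) at every timepoint.  With two within levels the design
reduces to exact closed forms on per-participant condition means `m_i`
and differences `d_i`: the group effect is a one-way ANOVA on `m_i`
against subjects-within-groups error; the condition effect tests the
*unweighted* mean of group-wise `d` means (the Type III hypothesis under
unbalanced groups, matching SPSS-style output); the interaction is a
one-way ANOVA on `d_i`; the latter two share the condition-by-subjects
error.  Partial eta squared is `SS_effect/(SS_effect+SS_error)`.

Family-wise error over timepoints is controlled by a bootstrap
max-cluster-sum procedure: data are centered within each group ×
condition cell; participants are resampled with replacement **within
group** (preserving the between-participants design and the group-size
imbalance — the resampling scope was unstated, and all-participants
resampling is available behind a flag); each of `n_boot` (default 2000)
draws contributes the maximum sum of F values over maximal contiguous
runs of pointwise-significant (p < .05) timepoints, with 0 recorded when
no timepoint is significant (keeping the null distribution proper).
The cluster threshold is the (1−α) quantile (α = .05) of these maxima;
observed clusters are significant when their F sum **strictly exceeds**
it.  Cluster adjacency is temporal only.  Follow-up two-group analyses
re-run the same machinery restricted to an omnibus cluster's window and
report the direction of the group difference per cluster; a pointwise
variant exists but the cluster-corrected form is the default, since the
follow-ups are themselves reported as clusters.  Planned simple
contrasts test each clinical group against the reference group on
condition-averaged scores using the pooled subjects-within-groups error.
Behavioural contrasts default to condition averages (per-level contrasts
are available).  Pearson correlations are pairwise-complete with
two-sided p values.

Validity at the sizes used here: over 200 simulated global-null
datasets (3 × 12 participants, 50 timepoints, 500 bootstrap iterations)
the empirical group-effect FWER is ~0.02–0.035 — controlled and, as
expected for max-statistic procedures, somewhat conservative.  An
injected 100 ms condition effect at SNR 1 is detected in ≥90% of
datasets, with power monotone in effect size.

## Pipeline and problem sizes

`run_full_pipeline` chains synth → preprocess → RCA (fitted on the TD
group, applied to all groups — the normative-weights design) →
waveforms → statistics per task, persisting every stage artifact
(CSV/HDF5/JSON) so stages re-run independently; a master seed spawns a
deterministic seed per stage via `SeedSequence`, making a run a pure
function of its config.  Default config mirrors the full study design
(group sizes 57/29/44, 72 trials per level, 2000 bootstrap iterations).
The test suite and the worked examples run reduced designs — typically
2–8 participants per group, 12–36 trials per level, 150–500 bootstrap
iterations, simulation windows of (−300, 700) ms — chosen so the whole
suite completes in minutes while every qualitative property (design
counts, artifact recall, component recovery, cluster localization,
FWER control) is still exercised; the methods are identical at full
scale.

## Known limitations

* The generator's linear, stationary mixture is far simpler than real
  EEG; recovery results bound pipeline correctness, not field
  performance.
* Reliability fractions depend on the eigenvalue-ratio definition;
  published percentages computed under other accountings are not
  comparable.
* The pairwise-complete covariance estimator is not guaranteed positive
  semi-definite under heavy, structured missingness; the subspace
  truncation absorbs mild violations, but extreme masking rates warrant
  inspection of the spectrum.
* Follow-up cluster analyses inherit the selection of the omnibus
  window; their p values are conditional on that selection, as in the
  procedure they reproduce.
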