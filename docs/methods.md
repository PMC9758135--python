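# Methods notes

## Generative model

Each simulated subject carries two condition-pattern pairs over `V`
voxels (default 70): a **sensory** pair (stimulus response to the left /
right feature) and a **preparatory** pair (delay-period activity under
attend-left / attend-right).  Both pairs decompose as
`mean_amplitude +/- (pattern_amplitude / 2) * axis`, where the axis is a
unit vector over voxels.  The sensory axis is drawn at random; the
preparatory axis is the Gram–Schmidt mix
`d_p = overlap * d_s + sqrt(1 - overlap^2) * d_orth`, so the cosine
between the two between-condition difference axes equals the requested
`overlap` to machine precision.  `overlap` is the scientific dial: 0
encodes a fully non-sensory preparatory template, 1 a sensory one.

Per trial the generator places a preparatory neural event (attention task
only) and a 0.5 s stimulus event.  The preparatory event is by default a
boxcar sustained from cue onset to stimulus onset (`prep_sustained=True`);
a transient 0.5 s alternative at the cue is available, and which of the
two better describes real preparation is left open on purpose.  Events
are convolved with a double-gamma HRF (positive lobe peaking at 5 s,
undershoot at 15 s, peak ratio 6) on a fine grid (22 samples per TR) and
sampled at TR = 2.2 s.

**Amplitude convention.**  Every event's convolved response is divided by
the peak response of an isolated event of the same duration, so amplitude
parameters read as "peak percent signal change of an isolated event".
Defaults: condition-common amplitudes 0.3 (preparation) and 1.0
(stimulus) PSC — a deliberately weak anticipatory elevation against a
robust stimulus response — and condition-specific pattern amplitudes 0.5
and 1.0 PSC along the respective axes.  Gaussian i.i.d. noise
(`noise_sd`, default 1.0 PSC per voxel-timepoint, roughly 3 T task-fMRI
magnitude) is added in PSC units, with optional AR(1) temporal
correlation and linear drift (both off by default so the preprocessing
stages have clean contracts); the PSC signal then modulates a raw
baseline level of 1000.

**Timing.**  Trial onsets accumulate nominal durations
(cue + delay + stimulus + ITI) and are snapped to the TR grid; both
nominal and snapped onsets are stored.  Delay counts per attention run
are exact (10/10/40/40% of trials at 1.7/3.9/6.1/8.3 s), making the 80%
long-delay property deterministic.  The baseline task's ITI range
(3.9–8.3 s) is discretized in TR steps by analogy with the attention
task.  Incorrect trials (Bernoulli behavior, default 75% accuracy) carry
the same patterns as correct ones unless `swap_pattern_on_incorrect` is
set, which models incorrect responses as misallocated attention.

## Preprocessing and deconvolution choices

* High-pass filtering is a joint orthogonal projection onto the
  complement of {constant, linear trend, DCT-II cosines below 0.01 Hz},
  per run.  A single projection (rather than detrend-then-filter) makes
  the operation exactly idempotent and edge-artifact-free.  Order of
  operations: PSC -> projection -> voxel pruning -> concatenation.
* The FIR design matrix receives the identical per-run filtering as the
  data (`filter_fir_design`).  Without it, the data's removed mean is
  absorbed into the betas as a negative offset and the FIR baseline loses
  its meaning on designs without rest periods; with it, noiseless
  condition time courses start at ~0 and peak at the embedded amplitudes.
* The attention-task GLM uses ten regressors of twelve bins: 2 attended
  directions x 2 long delays for correct trials, one regressor per short
  delay for correct trials, and one regressor per delay for incorrect
  trials.  The 4 + 2 + 4 grouping of the incorrect trials is a documented
  choice (the alternative two-regressor grouping would change the total);
  it is configurable through the FIR spec.
* No intercept column: data are filtered PSC with per-run mean ~0; r² is
  still computed about each voxel's mean.  Rank-deficient designs (e.g. a
  condition with no trials) fall back to the minimum-norm pseudoinverse
  solution with zero betas in the empty columns.
* "k TRs after onset" means FIR bin index k, with bin 0 at the onset TR.
  Stimulus-anchored windows are located at bin offset
  `round((cue + delay) / TR)` (3 and 4 for the two long delays).

## Baseline shift index

`BSI = max(preparation window) / max(stimulus window)` on the
condition-averaged, voxel-averaged FIR time course, windows 1–3 TRs after
trial onset and after stimulus onset, long-delay correct trials, stimulus
segments averaged across the two long delays before taking the max.

Recovery is attenuated by HRF overlap.  With the sustained default, the
preparatory BOLD response is still rising inside the 1–3 TR window and
keeps rising past stimulus onset, where it inflates the stimulus peak:
for an embedded amplitude ratio of 0.3 the noiseless recovered BSI is
**0.19** (computed from the generative convolution oracle and frozen in
the tests).  The documented bias bound is |BSI − ratio| < 0.12.  With the
transient preparatory mode the response peaks inside the window and the
noiseless BSI recovers 0.30 within 0.05.  A non-positive stimulus peak
raises an explicit error and excludes the subject from group BSI
statistics.

## Decoding choices

* Patterns are window means (2–3 TRs) of the filtered PSC series, one row
  per retained trial (attention: long-delay and correct, both toggles
  exposed; baseline: all trials).
* Z-scoring is per voxel across trials with both conditions pooled.
  Inside cross-validation the statistics come from the training fold only
  and are applied to the test fold; a `paper_mode_znorm` flag instead
  normalizes the whole set once before folding, matching the common
  single-pass description.  Cross-task decoding normalizes each task's
  set within itself.
* The FLD uses diagonal-loading shrinkage
  `S_lambda = (1 - lambda) S + lambda * trace(S)/V * I` with
  `lambda = 0.05` by default — with ~70 voxels against ~110 trials the
  unshrunk pooled covariance is poorly conditioned.  Ties at decision
  score 0 deterministically take the lexicographically smaller label.
* Permutations shuffle training labels only and rerun the identical
  pipeline.  The group null averages the subjects' permutation vectors
  index-wise (subject seeds are independent, so the pairing is
  arbitrary); the threshold is the nearest-rank 95th percentile; p-values
  use the +1 correction, `p = (1 + #{null >= obs}) / (1 + n_perm)`, so
  they are never 0.

## Statistics

Repeated-measures ANOVAs use the standard within-subject partitioning
with each effect tested against its own effect x subject interaction and
uncorrected degrees of freedom (Greenhouse–Geisser available as an
option).  For a 2 x 10 within-subject design this yields df = (1, 11)
for the period main effect.  The JZS paired Bayes factor integrates the
noncentral-t likelihood against a Cauchy(0, 0.707) effect-size prior by
adaptive quadrature; for t = 1.71, n = 12 it gives BF10 = 0.89
(BF01 = 1.12), matching the independent pingouin implementation to four
digits.  Cousineau error bars recenter each subject before computing
per-condition SEMs; the Morey factor `sqrt(C/(C-1))` is available via a
flag.  Benjamini–Hochberg adjustment is delegated to statsmodels and
cross-checked against a brute-force step-up oracle in the tests.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes:
event-related BOLD with known HRF, controlled pattern geometry, i.i.d.
(optionally AR(1)) noise, run structure, and behavioral label noise.  It
does **not** emulate 3-D spatial structure, head motion, physiological
noise, voxel-wise HRF variability, or retinotopic receptive fields
(quadrant labels are generator metadata).  Passing recovery tests
therefore validates the estimators and inference machinery — not claims
about real cortical data.

Two emergent properties are worth knowing when choosing parameters:

* the 0.01 Hz high-pass removes a substantial share of the slow,
  HRF-smoothed condition-difference signal (separations drop by ~0.15 PSC
  at default amplitudes for both periods), exactly as in real slow
  event-related designs;
* responses of adjacent trials overlap, so the previous trial's stimulus
  pattern leaks into the current preparatory window.  At `overlap=1` this
  carry-over lies along the preparatory discriminant axis and degrades
  preparation-period decoding unless the preparatory amplitude is raised
  — the dissociation experiments use `pattern_amplitude_prep=2.5,
  pattern_amplitude_stim=2.0, noise_sd=0.3`, chosen so stimulus decoding
  is near ceiling while preparation stays decodable at both overlap
  extremes.

## Problem sizes used by the test and acceptance runs

Chance calibration averages eight independent 12-subject null cohorts
(70 voxels, 6 runs x 30 trials) — a single cohort's group mean carries a
Monte-Carlo sd of ~0.019, so the average makes the stated 0.02 tolerance
a ~3-sigma check of the same quantity.  The permutation type-I experiment
uses 200 replicates of reduced cohorts (6 subjects, 20 voxels, 2 runs,
200 permutations), judged against the binomial 99% band around the
nominal 0.05.  The dissociation experiments use 12 subjects, 70 voxels
and 200 permutations.  All defaults elsewhere are the full study sizes.
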