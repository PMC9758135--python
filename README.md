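# preptemplate

Synthetic-data reimplementation of a preparatory feature-attention fMRI
analysis: multivoxel BOLD simulation for a cued motion-direction attention
task, FIR deconvolution, baseline-shift univariate statistics, and
cross-validated / cross-task multivoxel decoding with permutation-based
group inference.

## The scientific problem

When an observer is cued to attend a visual feature (say, leftward vs
rightward motion) before the stimulus appears, the brain carries a
*preparatory template* of the attended feature through the delay.  Two
hypotheses describe its format:

* **sensory template** — preparatory activity patterns resemble those
  evoked by actually perceiving the feature, so a decoder trained on
  responses to a single presented feature (a separate *baseline task*)
  should read out the preparatory patterns;
* **non-sensory (abstract) template** — the to-be-attended feature is
  decodable during preparation, but from patterns unrelated to the
  sensory response, so the baseline-trained decoder generalizes to the
  stimulus period yet fails on the preparatory period.

Real data cannot tell you which pattern geometry generated them.  A
simulation can: this package embeds condition-specific voxel patterns for
the preparatory and stimulus periods whose *difference-axis overlap* is a
ground-truth dial (`overlap` = cosine between the preparatory and sensory
between-condition axes, 0 = fully non-sensory, 1 = fully sensory), and
asks whether the full analysis chain recovers the dissociation.

## What is simulated

The attention task: a 0.5 s cue, a delay of 1.7/3.9/6.1/8.3 s with exact
10/10/40/40% frequencies (80% long delays), a 0.5 s compound stimulus,
and ITIs of 4.4–8.8 s in 2.2 s steps; 6 runs x 30 trials per subject,
behavioral accuracy ~75% (Bernoulli).  The baseline task: a single 0.5 s
feature, ITI 3.9–8.3 s, 2 runs x 61 trials.  Events (a sustained
delay-period boxcar plus a stimulus transient, each carrying its
condition's voxel pattern in peak percent-signal-change units) are
convolved with a double-gamma HRF, sampled at TR = 2.2 s, expressed as
percent modulation of a baseline level, and summed with Gaussian noise.

## The analysis chain

1. **preprocess** — percent signal change per run, joint removal of the
   constant/linear/low-frequency (< 0.01 Hz) confounds, pruning of voxels
   exceeding 10% signal change, run concatenation.
2. **deconvolve** — finite-impulse-response GLM (10 regressors x 12 bins
   for the attention task, 2 x 8 for the baseline task), pseudoinverse
   fit, per-voxel r², top-70 voxel selection.  The design matrix receives
   the same temporal filtering as the data.
3. **univariate** — condition time courses, window amplitudes, and the
   baseline shift index `BSI = peak(preparation) / peak(stimulus)` from
   the 1–3 TR windows, plus a quadrant-based covert-spatial-attention
   control contrast.
4. **mvpa** — single-trial patterns (window mean 2–3 TRs after trial or
   stimulus onset; long-delay correct trials), per-voxel z-scoring,
   shrinkage Fisher linear discriminant (`w = S_lambda^{-1} (mu+ - mu-)`),
   leave-one-run-out cross-validation, baseline-to-attention cross-task
   generalization, and a group permutation test: per subject the training
   labels are shuffled (default 1000 times), subjects' null distributions
   are averaged, and the observed group mean is compared to the null's
   95th percentile.
5. **stats** — paired/one-sample t-tests, one- and two-way
   repeated-measures ANOVA, JZS Bayes factors, Benjamini–Hochberg FDR,
   Cousineau within-subject error bars.

## Worked example

```python
import preptemplate as pt
from preptemplate.pipeline import PipelineConfig, run_experiment

cfg = PipelineConfig(
    cohort=pt.CohortSpec(n_subjects=12, n_voxels=70, seed=7),
    overlap=0.0,                 # preparatory axis orthogonal to sensory axis
    noise_sd=0.3, pattern_amplitude_stim=2.0, pattern_amplitude_prep=2.5,
    n_perm=200)
bundle = run_experiment(cfg)
print(bundle.tables["decoding_group"])
```

prints (abbreviated):

```
scheme      period  accuracy  threshold_95  p_perm  p_fdr
  loro preparation     0.789         0.526   0.005  0.006
  loro    stimulus     0.961         0.530   0.005  0.006
  loro    baseline     0.913         0.518   0.005  0.006
 cross preparation     0.430         0.548   0.990  0.990
 cross    stimulus     0.975         0.563   0.005  0.006
```

Reading: within-task decoding (leave-one-run-out, `loro`) finds the
attended direction in both the preparatory (0.79) and stimulus (0.96)
periods, and the baseline task decodes its own feature (0.91).  The
baseline-trained classifier transfers to the stimulus period (0.97,
significant against the permutation threshold) but sits at chance on the
preparatory period (0.43, p = 0.99) — the non-sensory-template signature,
correct here because the cohort was generated with `overlap=0`.  Re-run
with `overlap=1.0` and the cross-task preparation row becomes
significant.  The accompanying BSI table reports a mean preparatory/
stimulus peak ratio of 0.19 for the embedded 0.3 amplitude ratio (see
`docs/methods.md` for the HRF-overlap attenuation).

The same experiment is available from the shell:

```sh
preptemplate run-all --seed 7 --subjects 12 --perms 200 --out results/demo
preptemplate verify --results results/demo      # bit-exact reproduction check
preptemplate simulate --subjects 2 --overlap 0 --seed 3 --out data/sim
```

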