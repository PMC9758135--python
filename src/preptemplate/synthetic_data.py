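"""Synthetic multivoxel BOLD cohorts for the cued feature-attention task.

The generator emulates two event-related designs:

* an **attention task**: a 0.5 s color cue indicates the to-be-attended
  motion direction, a variable delay (1.7/3.9/6.1/8.3 s at 10/10/40/40%)
  follows, then a 0.5 s compound stimulus, then an inter-trial interval of
  4.4-8.8 s in 2.2 s steps; 6 runs of 30 trials by default;
* a **baseline task**: a single 0.5 s moving-dot stimulus followed by an
  ITI of 3.9-8.3 s; 2-3 runs of 61 trials by default.

Each simulated subject carries a :class:`GroundTruth`: condition-specific
multivoxel amplitude patterns for the preparatory (delay) period and for
the stimulus response.  The cosine similarity between the two conditions'
*difference axes* (preparatory vs sensory) is the ``overlap`` parameter --
the generative counterpart of the sensory-template question: with
``overlap=1`` preparation re-uses the sensory pattern axis, with
``overlap=0`` it lives on an orthogonal, non-sensory axis.

Neural events (sustained delay-period boxcar plus a transient stimulus)
are convolved with a double-gamma HRF, sampled on the TR grid, expressed
as percent modulation of a baseline signal level, and summed with Gaussian
noise, so that the downstream FIR deconvolution has a realistic estimation
problem with known answers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from ._exceptions import InvalidDesignError, ParameterError, ShapeError
from .containers import VoxelTimeSeries

__all__ = [
    "TR_DEFAULT", "CUE_DURATION", "STIM_DURATION",
    "ATTENTION_DELAYS", "ATTENTION_DELAY_PROPORTIONS", "ATTENTION_ITIS",
    "BASELINE_ITIS", "ATTENTION_CONDITIONS", "BASELINE_CONDITIONS",
    "QUADRANTS", "HRFParams", "TrialEvent", "TaskDesign", "GroundTruth",
    "CohortSpec", "SimulatedSubject",
    "make_attention_design", "make_baseline_design", "simulate_behavior",
    "make_ground_truth", "render_bold", "generate_cohort",
    "double_gamma_hrf", "attended_quadrants",
]

# Timing constants of the scanned task (seconds).
TR_DEFAULT = 2.2
CUE_DURATION = 0.5
STIM_DURATION = 0.5
ATTENTION_DELAYS = (1.7, 3.9, 6.1, 8.3)
ATTENTION_DELAY_PROPORTIONS = (0.1, 0.1, 0.4, 0.4)
ATTENTION_ITIS = (4.4, 6.6, 8.8)
# The baseline task's ITI is stated only as a 3.9-8.3 s range; by analogy
# with the attention task we discretize it in TR (2.2 s) steps.
BASELINE_ITIS = (3.9, 6.1, 8.3)
ATTENTION_CONDITIONS = ("attend_left", "attend_right")
BASELINE_CONDITIONS = ("left", "right")
QUADRANTS = ("UL", "UR", "LL", "LR")

#: maps attention-task condition names onto the feature they share with the
#: baseline task (the attended/presented motion direction).
CONDITION_FEATURE = {
    "attend_left": "left", "attend_right": "right",
    "left": "left", "right": "right",
}


# --------------------------------------------------------------------------
# hemodynamic response
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF: response peak, undershoot peak and peak/undershoot ratio."""
    peak: float = 5.0
    undershoot: float = 15.0
    ratio: float = 6.0


def double_gamma_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (s), peak-normalized to 1.

    Gamma densities with unit scale peak at ``shape - 1``, so the positive
    lobe uses shape ``peak + 1`` and the undershoot shape ``undershoot + 1``.
    """
    t = np.asarray(t, dtype=float)
    h = (gamma_dist.pdf(t, params.peak + 1.0)
         - gamma_dist.pdf(t, params.undershoot + 1.0) / params.ratio)
    peak = h.max()
    if peak <= 0:
        raise ParameterError("degenerate HRF parameters (non-positive peak)")
    return h / peak


# --------------------------------------------------------------------------
# task designs
# --------------------------------------------------------------------------

@dataclass
class TrialEvent:
    """One trial: snapped/nominal onset, condition, delay (attention only), ITI."""
    onset: float                 # seconds from run start, snapped to the TR grid
    condition: str
    iti: float
    delay: float | None = None   # cue-to-stimulus interval; None for baseline task
    correct: bool = True
    onset_nominal: float | None = None
    run_id: int | None = None

    def stimulus_onset(self, cue_duration: float = CUE_DURATION) -> float:
        """Stimulus onset in seconds (equals trial onset for the baseline task)."""
        if self.delay is None:
            return self.onset
        return self.onset + cue_duration + self.delay


@dataclass
class TaskDesign:
    """One run's (or concatenated runs') ordered trial list plus timing constants."""
    run_id: int
    task: str                    # "attention" | "baseline"
    trials: list
    tr: float
    n_timepoints: int
    cue_mapping: str = "mapping_A"
    cue_duration: float = CUE_DURATION
    stim_duration: float = STIM_DURATION

    def __post_init__(self):
        if self.task not in ("attention", "baseline"):
            raise ParameterError(f"unknown task {self.task!r}")
        if self.cue_mapping not in ("mapping_A", "mapping_B"):
            raise ParameterError(f"unknown cue_mapping {self.cue_mapping!r}")
        onsets = [t.onset for t in self.trials]
        if any(o < 0 for o in onsets):
            raise InvalidDesignError("negative trial onset")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InvalidDesignError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration(self) -> float:
        return self.n_timepoints * self.tr

    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])


def _trial_duration(task: str, delay: float | None, iti: float) -> float:
    if task == "attention":
        return CUE_DURATION + delay + STIM_DURATION + iti
    return STIM_DURATION + iti


def _assemble_design(run_id, task, conditions, delays, itis, tr, tail_trs,
                     cue_mapping) -> TaskDesign:
    """Lay trials end to end; snap onsets to the TR grid, keep nominal onsets."""
    trials = []
    t_nominal = 0.0
    for i, cond in enumerate(conditions):
        delay = None if delays is None else delays[i]
        snapped = round(round(t_nominal / tr) * tr, 10)
        trials.append(TrialEvent(onset=snapped, condition=cond, iti=itis[i],
                                 delay=delay, onset_nominal=t_nominal,
                                 run_id=run_id))
        t_nominal += _trial_duration(task, delay, itis[i])
    n_timepoints = int(np.ceil(t_nominal / tr - 1e-9)) + tail_trs
    return TaskDesign(run_id=run_id, task=task, trials=trials, tr=tr,
                      n_timepoints=n_timepoints, cue_mapping=cue_mapping)


def make_attention_design(run_id: int, n_trials: int = 30, tr: float = TR_DEFAULT,
                          seed: int | SeedSequence = 0, *, tail_trs: int = 4,
                          cue_mapping: str = "mapping_A") -> TaskDesign:
    """Generate one attention-task run.

    Delay counts are exact (``n_trials`` x 10/10/40/40%), so 80% of trials
    are long-delay by construction; conditions are balanced (half each) and
    the order of both is shuffled by ``seed``.  ITIs are drawn uniformly
    from {4.4, 6.6, 8.8} s.  Onsets are snapped to the TR grid (nominal
    onsets are kept on each trial).
    """
    if n_trials % 10 != 0:
        raise InvalidDesignError(
            f"n_trials must be divisible by 10 for exact delay proportions, got {n_trials}")
    if n_trials % 2 != 0:
        raise InvalidDesignError(f"n_trials must be even, got {n_trials}")
    if tr <= 0:
        raise ParameterError(f"tr must be positive, got {tr}")
    rng = default_rng(seed)
    delays = np.repeat(ATTENTION_DELAYS,
                       [int(round(n_trials * p)) for p in ATTENTION_DELAY_PROPORTIONS])
    delays = rng.permutation(delays)
    conditions = rng.permutation(
        np.repeat(ATTENTION_CONDITIONS, n_trials // 2))
    itis = rng.choice(ATTENTION_ITIS, size=n_trials)
    return _assemble_design(run_id, "attention", conditions, delays, itis, tr,
                            tail_trs, cue_mapping)


def make_baseline_design(run_id: int, n_trials: int = 61, tr: float = TR_DEFAULT,
                         seed: int | SeedSequence = 0, *, tail_trs: int = 4) -> TaskDesign:
    """Generate one baseline-task run (single feature, no cue/delay period).

    Conditions are as balanced as possible (counts differ by at most 1 for
    odd ``n_trials``); ITIs are drawn uniformly from {3.9, 6.1, 8.3} s.
    """
    if n_trials < 2:
        raise InvalidDesignError(f"need at least 2 trials, got {n_trials}")
    if tr <= 0:
        raise ParameterError(f"tr must be positive, got {tr}")
    rng = default_rng(seed)
    base = np.repeat(BASELINE_CONDITIONS, n_trials // 2)
    if n_trials % 2:
        base = np.append(base, rng.choice(BASELINE_CONDITIONS))
    conditions = rng.permutation(base)
    itis = rng.choice(BASELINE_ITIS, size=n_trials)
    return _assemble_design(run_id, "baseline", conditions, None, itis, tr,
                            tail_trs, "mapping_A")


def simulate_behavior(design: TaskDesign, accuracy: float = 0.75,
                      seed: int | SeedSequence = 0) -> TaskDesign:
    """Assign each trial's correct flag as an independent Bernoulli(accuracy) draw.

    The ~75% level emulates a threshold staircase having converged before
    scanning; the staircase itself is not simulated.
    """
    if not (0.0 < accuracy <= 1.0):
        raise ParameterError(f"accuracy must be in (0, 1], got {accuracy}")
    rng = default_rng(seed)
    flags = rng.random(design.n_trials) < accuracy
    trials = [dataclasses.replace(t, correct=bool(f))
              for t, f in zip(design.trials, flags)]
    return dataclasses.replace(design, trials=trials)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator embeds and the recovery analyses try to recover.

    ``sensory_pattern``/``prep_pattern`` map the feature ('left'/'right')
    to a per-voxel peak-PSC amplitude vector.  ``overlap`` is the cosine of
    the angle between the two between-condition difference axes.
    """
    n_voxels: int
    sensory_pattern: dict
    prep_pattern: dict
    overlap: float
    mean_amplitude_prep: float
    mean_amplitude_stim: float
    pattern_amplitude_prep: float
    pattern_amplitude_stim: float
    noise_sd: float
    baseline_level: float
    quadrant_map: np.ndarray
    hrf_params: HRFParams = HRFParams()
    sensory_axis: np.ndarray | None = None   # unit difference axes, for diagnostics
    prep_axis: np.ndarray | None = None
    # noise / nuisance model
    ar_rho: float = 0.0
    drift_psc: float = 0.0          # total linear drift over a run, in PSC
    # behavioural / strategic flags probed by recovery tests
    prep_sustained: bool = True     # delay-period signal: boxcar vs transient at cue
    swap_pattern_on_incorrect: bool = False
    quadrant_bias: float = 0.0      # extra preparatory PSC in attended quadrants
    quadrant_bias_layout: str = "upper_two"


def attended_quadrants(feature: str, layout: str) -> tuple:
    """Quadrants hypothetically attended under a covert-spatial strategy.

    ``upper_two``: leftward -> UL, rightward -> UR (contrast within the two
    upper quadrants).  ``diagonal_four``: leftward -> UL+LR, rightward ->
    UR+LL (attention spread along the motion diagonal).
    """
    if layout == "upper_two":
        return ("UL",) if feature == "left" else ("UR",)
    if layout == "diagonal_four":
        return ("UL", "LR") if feature == "left" else ("UR", "LL")
    raise ParameterError(f"unknown quadrant layout {layout!r}")


def make_ground_truth(n_voxels: int = 70, overlap: float = 0.0, *,
                      mean_amplitude_prep: float = 0.3,
                      mean_amplitude_stim: float = 1.0,
                      pattern_amplitude_prep: float = 0.5,
                      pattern_amplitude_stim: float = 1.0,
                      noise_sd: float = 1.0,
                      baseline_level: float = 1000.0,
                      seed: int | SeedSequence = 0,
                      hrf_params: HRFParams = HRFParams(),
                      **flags) -> GroundTruth:
    """Construct per-voxel condition patterns with a controlled axis overlap.

    The sensory difference axis ``d_s`` is a random unit vector; the
    preparatory axis is the Gram-Schmidt mix
    ``d_p = overlap * d_s + sqrt(1 - overlap^2) * d_orth`` with ``d_orth`` a
    random unit vector orthogonal to ``d_s``, so ``cos(d_s, d_p)`` equals
    the requested overlap to machine precision.  Condition patterns are
    ``mean +/- (pattern_amplitude / 2) * axis``.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ParameterError(f"overlap must be in [0, 1], got {overlap}")
    if n_voxels < 2:
        raise ParameterError(f"need at least 2 voxels, got {n_voxels}")
    rng = default_rng(seed)

    def unit(v):
        return v / np.linalg.norm(v)

    d_s = unit(rng.standard_normal(n_voxels))
    z = rng.standard_normal(n_voxels)
    d_orth = unit(z - (z @ d_s) * d_s)
    d_p = overlap * d_s + np.sqrt(max(0.0, 1.0 - overlap ** 2)) * d_orth

    sensory = {
        "left": mean_amplitude_stim + 0.5 * pattern_amplitude_stim * d_s,
        "right": mean_amplitude_stim - 0.5 * pattern_amplitude_stim * d_s,
    }
    prep = {
        "left": mean_amplitude_prep + 0.5 * pattern_amplitude_prep * d_p,
        "right": mean_amplitude_prep - 0.5 * pattern_amplitude_prep * d_p,
    }
    quadrant_map = np.array([QUADRANTS[i % 4] for i in range(n_voxels)])
    return GroundTruth(
        n_voxels=n_voxels, sensory_pattern=sensory, prep_pattern=prep,
        overlap=overlap, mean_amplitude_prep=mean_amplitude_prep,
        mean_amplitude_stim=mean_amplitude_stim,
        pattern_amplitude_prep=pattern_amplitude_prep,
        pattern_amplitude_stim=pattern_amplitude_stim,
        noise_sd=noise_sd, baseline_level=baseline_level,
        quadrant_map=quadrant_map, hrf_params=hrf_params,
        sensory_axis=d_s, prep_axis=d_p, **flags)


# --------------------------------------------------------------------------
# BOLD rendering
# --------------------------------------------------------------------------

def _hrf_kernel(dt: float, params: HRFParams, length_s: float = 32.0) -> np.ndarray:
    t = np.arange(0.0, length_s, dt)
    return double_gamma_hrf(t, params)


def _event_shape_peak(duration: float, dt: float, kernel: np.ndarray) -> float:
    """Peak of (unit boxcar of ``duration``) * HRF on the fine grid."""
    n = max(1, int(round(duration / dt)))
    box = np.ones(n)
    return float(fftconvolve(box, kernel).max())


def render_bold(design: TaskDesign, truth: GroundTruth,
                seed: int | SeedSequence = 0, *, oversample: int = 22) -> VoxelTimeSeries:
    """Render one run's raw-unit BOLD data from a design and a ground truth.

    Every trial contributes a preparatory neural event (attention task
    only; a boxcar from cue onset to stimulus onset by default, or a 0.5 s
    transient at the cue if ``truth.prep_sustained`` is off) carrying
    ``prep_pattern[feature]``, and a 0.5 s stimulus event carrying
    ``sensory_pattern[feature]``.  Events are convolved with the
    double-gamma HRF on a fine grid (``oversample`` points per TR) and each
    event's response is normalized by the peak response of an isolated
    event of the same duration, so amplitude parameters read as "peak PSC
    of an isolated event".  Overlapping trials superpose.  The PSC signal
    plus Gaussian noise (optionally AR(1)) and an optional linear drift is
    then expressed as raw units: ``baseline_level * (1 + psc / 100)``.
    """
    for cond in set(CONDITION_FEATURE[t.condition] for t in design.trials):
        for patt in (truth.sensory_pattern, truth.prep_pattern):
            if len(np.asarray(patt[cond])) != truth.n_voxels:
                raise ShapeError("pattern length inconsistent with n_voxels")
    tr, T, V = design.tr, design.n_timepoints, truth.n_voxels
    dt = tr / oversample
    n_hi = T * oversample
    kernel = _hrf_kernel(dt, truth.hrf_params)

    # Group events by (component, feature, duration): events in a group share
    # both the voxel pattern and the peak-normalization constant, so one
    # convolution per group suffices.
    groups: dict = {}

    def add_event(comp, feature, start, duration):
        key = (comp, feature, round(duration, 6))
        train = groups.setdefault(key, np.zeros(n_hi))
        i0 = int(round(start / dt))
        i1 = min(n_hi, i0 + max(1, int(round(duration / dt))))
        if i0 < n_hi:
            train[i0:i1] += 1.0

    for trial in design.trials:
        feature = CONDITION_FEATURE[trial.condition]
        if truth.swap_pattern_on_incorrect and not trial.correct:
            feature = "right" if feature == "left" else "left"
        stim_on = trial.stimulus_onset(design.cue_duration)
        if design.task == "attention":
            prep_dur = (stim_on - trial.onset) if truth.prep_sustained else design.cue_duration
            add_event("prep", feature, trial.onset, prep_dur)
        add_event("stim", feature, stim_on, design.stim_duration)

    psc = np.zeros((V, T))
    for (comp, feature, dur), train in groups.items():
        resp_hi = fftconvolve(train, kernel)[:n_hi] / _event_shape_peak(dur, dt, kernel)
        resp_tr = resp_hi[::oversample]
        if comp == "prep":
            amp = np.asarray(truth.prep_pattern[feature], dtype=float).copy()
            if truth.quadrant_bias != 0.0:
                att = attended_quadrants(feature, truth.quadrant_bias_layout)
                amp = amp + truth.quadrant_bias * np.isin(truth.quadrant_map, att)
        else:
            amp = np.asarray(truth.sensory_pattern[feature], dtype=float)
        psc += np.outer(amp, resp_tr)

    rng = default_rng(seed)
    if truth.noise_sd > 0:
        eps = rng.standard_normal((V, T)) * truth.noise_sd
        if truth.ar_rho != 0.0:
            rho = truth.ar_rho
            ar = np.empty_like(eps)
            ar[:, 0] = eps[:, 0]
            scale = np.sqrt(1.0 - rho ** 2)
            for t in range(1, T):
                ar[:, t] = rho * ar[:, t - 1] + scale * eps[:, t]
            eps = ar
        psc = psc + eps
    if truth.drift_psc != 0.0:
        psc = psc + truth.drift_psc * (np.linspace(0.0, 1.0, T) - 0.5)

    raw = truth.baseline_level * (1.0 + psc / 100.0)
    return VoxelTimeSeries(data=raw, tr=tr, run_id=design.run_id, units="raw",
                           history=["render_bold"])


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-level design constants for a simulated cohort."""
    n_subjects: int = 12
    n_attention_runs: int = 6
    n_baseline_runs: int = 2
    n_attention_trials: int = 30
    n_baseline_trials: int = 61
    n_voxels: int = 70
    behavioral_accuracy: float = 0.75
    tr: float = TR_DEFAULT
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_attention_runs", "n_baseline_runs",
                     "n_attention_trials", "n_baseline_trials", "n_voxels"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not (0.0 < self.behavioral_accuracy <= 1.0):
            raise ParameterError("behavioral_accuracy must be in (0, 1]")


@dataclass
class SimulatedSubject:
    subject_id: int
    truth: GroundTruth
    attention_designs: list
    baseline_designs: list
    attention_runs: list     # list[VoxelTimeSeries], raw units
    baseline_runs: list


def generate_cohort(spec: CohortSpec, overlap: float = 0.0,
                    **truth_kwargs) -> list:
    """Simulate ``spec.n_subjects`` subjects sharing an overlap level.

    Each subject gets an independent :class:`GroundTruth` (fresh random
    axes, shared parameters), freshly randomized run designs, Bernoulli
    behavior at ``spec.behavioral_accuracy``, and rendered BOLD runs.  The
    cue mapping reverses halfway through the attention runs.  Fully
    reproducible from ``spec.seed``; extra keyword arguments are forwarded
    to :func:`make_ground_truth`.
    """
    root = SeedSequence(spec.seed)
    subjects = []
    for sid, subj_ss in enumerate(root.spawn(spec.n_subjects)):
        (truth_ss, design_ss, behav_ss, render_ss) = subj_ss.spawn(4)
        truth = make_ground_truth(spec.n_voxels, overlap, seed=truth_ss,
                                  **truth_kwargs)
        att_designs, att_runs = [], []
        d_children = design_ss.spawn(spec.n_attention_runs + spec.n_baseline_runs)
        b_children = behav_ss.spawn(spec.n_attention_runs + spec.n_baseline_runs)
        r_children = render_ss.spawn(spec.n_attention_runs + spec.n_baseline_runs)
        half = spec.n_attention_runs / 2.0
        for r in range(spec.n_attention_runs):
            mapping = "mapping_A" if r < half else "mapping_B"
            d = make_attention_design(r, spec.n_attention_trials, spec.tr,
                                      seed=d_children[r], cue_mapping=mapping)
            d = simulate_behavior(d, spec.behavioral_accuracy, seed=b_children[r])
            att_designs.append(d)
            att_runs.append(render_bold(d, truth, seed=r_children[r]))
        base_designs, base_runs = [], []
        for r in range(spec.n_baseline_runs):
            j = spec.n_attention_runs + r
            d = make_baseline_design(r, spec.n_baseline_trials, spec.tr,
                                     seed=d_children[j])
            d = simulate_behavior(d, spec.behavioral_accuracy, seed=b_children[j])
            base_designs.append(d)
            base_runs.append(render_bold(d, truth, seed=r_children[j]))
        subjects.append(SimulatedSubject(
            subject_id=sid, truth=truth,
            attention_designs=att_designs, baseline_designs=base_designs,
            attention_runs=att_runs, baseline_runs=base_runs))
    return subjects
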