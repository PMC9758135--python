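"""Univariate measures: window amplitudes, baseline shift index, quadrant contrast.

All measures operate on condition-wise FIR beta time courses (bins after
trial onset, in TR units).  Bin-offset convention: "k TRs after onset"
means FIR bin index k, with bin 0 at the onset TR itself.  Stimulus-
anchored windows are located inside the trial-anchored FIR using the
trial's delay: stimulus bin offset = round((cue + delay) / TR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._exceptions import (DegenerateDataError, DegenerateGroupingError,
                          EmptySelectionError,
                          ParameterError, UndefinedBSIError, WindowError)
from .deconvolve import LONG_DELAYS, DeconvolutionFit
from .synthetic_data import CUE_DURATION, attended_quadrants
from .stats import TTestResult, paired_t

logger = logging.getLogger(__name__)

__all__ = ["WindowSpec", "BSIResult", "QuadrantContrastResult",
           "condition_timecourse", "window_amplitude", "compute_bsi",
           "quadrant_contrast", "stimulus_bin_offset"]


@dataclass(frozen=True)
class WindowSpec:
    """Inclusive bin window counted from an anchor (trial or stimulus onset)."""
    anchor: str = "trial_onset"      # "trial_onset" | "stimulus_onset"
    start_tr: int = 2
    end_tr: int = 3

    def __post_init__(self):
        if self.anchor not in ("trial_onset", "stimulus_onset"):
            raise ParameterError(f"unknown anchor {self.anchor!r}")
        if not (0 <= self.start_tr <= self.end_tr):
            raise ParameterError(
                f"need 0 <= start_tr <= end_tr, got [{self.start_tr}, {self.end_tr}]")


@dataclass
class BSIResult:
    """Baseline shift index: peak preparatory / peak stimulus response."""
    value: float
    prep_peak: float
    stim_peak: float


@dataclass
class QuadrantContrastResult:
    """Per-subject attended/unattended means plus the group paired t-test."""
    attended_means: np.ndarray
    unattended_means: np.ndarray
    ttest: TTestResult
    hypothesis: str


def stimulus_bin_offset(delay: float, tr: float,
                        cue_duration: float = CUE_DURATION) -> int:
    """FIR bin offset of the stimulus onset within a trial-anchored response."""
    return int(round((cue_duration + delay) / tr))


def condition_timecourse(fit: DeconvolutionFit, labels, voxels=None) -> np.ndarray:
    """Mean FIR beta time course over the given labels and voxel indices."""
    labels = list(labels)
    missing = [lab for lab in labels if lab not in fit.betas]
    if missing:
        raise ParameterError(f"labels not in fit: {missing}")
    if voxels is not None:
        voxels = np.asarray(voxels)
        if voxels.size == 0:
            raise EmptySelectionError("empty voxel selection")
    stacks = []
    for lab in labels:
        b = fit.betas[lab]
        stacks.append(b if voxels is None else b[:, voxels])
    return np.mean([s.mean(axis=1) for s in stacks], axis=0)


def window_amplitude(timecourse: np.ndarray, window: WindowSpec,
                     anchor_bin: int = 0) -> float:
    """Mean of bins ``anchor_bin + start_tr .. anchor_bin + end_tr`` (inclusive)."""
    tc = np.asarray(timecourse, dtype=float)
    lo = anchor_bin + window.start_tr
    hi = anchor_bin + window.end_tr
    if lo < 0 or hi >= tc.size:
        raise WindowError(
            f"window bins [{lo}, {hi}] outside time course of length {tc.size}")
    return float(tc[lo:hi + 1].mean())


def compute_bsi(fit: DeconvolutionFit, tr: float,
                prep_window: WindowSpec = WindowSpec("trial_onset", 1, 3),
                stim_window: WindowSpec = WindowSpec("stimulus_onset", 1, 3),
                conditions=("attend_left", "attend_right"),
                long_delays=LONG_DELAYS, voxels=None) -> BSIResult:
    """Baseline shift index from long-delay correct-trial FIR betas.

    The condition-averaged, voxel-averaged time course is computed per long
    delay; the preparatory peak is the max over ``prep_window`` bins after
    trial onset (delay-averaged), the stimulus peak the max over
    ``stim_window`` bins after the delay-specific stimulus bin (segments
    aligned at stimulus onset, averaged across the two long delays, then
    maximized).  BSI = prep_peak / stim_peak.
    """
    if prep_window.anchor != "trial_onset" or stim_window.anchor != "stimulus_onset":
        raise ParameterError("prep window must anchor at trial onset and "
                             "stim window at stimulus onset")
    per_delay = []
    stim_segments = []
    for d in long_delays:
        tc = condition_timecourse(
            fit, [f"{cond}_{d}" for cond in conditions], voxels)
        per_delay.append(tc)
        k = stimulus_bin_offset(d, tr)
        lo, hi = k + stim_window.start_tr, k + stim_window.end_tr
        if hi >= tc.size:
            raise WindowError(f"stimulus window [{lo}, {hi}] exceeds "
                              f"{tc.size} FIR bins for delay {d}")
        stim_segments.append(tc[lo:hi + 1])
    prep_tc = np.mean(per_delay, axis=0)
    prep_peak = float(prep_tc[prep_window.start_tr:prep_window.end_tr + 1].max())
    stim_peak = float(np.mean(stim_segments, axis=0).max())
    if stim_peak <= 0:
        raise UndefinedBSIError(
            f"non-positive stimulus peak ({stim_peak:.4g}); BSI undefined")
    return BSIResult(value=prep_peak / stim_peak,
                     prep_peak=prep_peak, stim_peak=stim_peak)


def quadrant_contrast(trial_sets, qmaps, hypothesis: str = "upper_two"
                      ) -> QuadrantContrastResult:
    """Covert-spatial-attention control: attended vs unattended quadrant response.

    ``trial_sets`` are per-subject preparatory-period
    :class:`~preptemplate.mvpa.TrialPatternSet` objects and ``qmaps`` the
    matching per-voxel quadrant labels.  Per subject and trial, voxels in
    the quadrants a spatial strategy would attend (leftward -> UL under
    ``upper_two``; UL+LR under ``diagonal_four``) are averaged against the
    counterpart quadrants; subject means feed a group paired t-test.
    """
    if hypothesis not in ("upper_two", "diagonal_four"):
        raise ParameterError(f"unknown hypothesis {hypothesis!r}")
    if len(trial_sets) != len(qmaps):
        raise ParameterError("need one quadrant map per subject")
    att_means, unatt_means = [], []
    for tps, qmap in zip(trial_sets, qmaps):
        qmap = np.asarray(qmap)
        if qmap.size != tps.patterns.shape[1]:
            raise ParameterError("quadrant map does not cover all voxels")
        a_vals, u_vals = [], []
        for row, label in zip(tps.patterns, tps.labels):
            feature = "left" if "left" in label else "right"
            att_q = attended_quadrants(feature, hypothesis)
            other = ("right" if feature == "left" else "left")
            unatt_q = attended_quadrants(other, hypothesis)
            att_mask = np.isin(qmap, att_q)
            unatt_mask = np.isin(qmap, unatt_q)
            if not att_mask.any() or not unatt_mask.any():
                raise DegenerateGroupingError(
                    "a quadrant grouping has zero voxels")
            a_vals.append(row[att_mask].mean())
            u_vals.append(row[unatt_mask].mean())
        att_means.append(np.mean(a_vals))
        unatt_means.append(np.mean(u_vals))
    att_means = np.asarray(att_means)
    unatt_means = np.asarray(unatt_means)
    try:
        ttest = paired_t(att_means, unatt_means)
    except DegenerateDataError:
        # exactly uniform responses: no contrast, report a null t
        logger.info("quadrant contrast has zero-variance differences; t set to 0")
        ttest = TTestResult(t=0.0, df=len(att_means) - 1, p=1.0, mean_diff=0.0)
    return QuadrantContrastResult(attended_means=att_means,
                                  unattended_means=unatt_means,
                                  ttest=ttest, hypothesis=hypothesis)
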