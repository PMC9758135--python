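"""FIR deconvolution: design construction, pseudoinverse fit, r², voxel selection.

Each regressor (condition label) is modeled as a set of free per-TR
impulse-response bins after trial onset; the stacked indicator design is
pseudo-inverted and multiplied by the time series, giving the
minimum-norm least-squares estimate of each condition's hemodynamic
response with no assumed shape.  The attention task uses ten regressors of
twelve bins (2 attended directions x 2 long delays for correct trials, one
per short delay for correct trials, one per delay for incorrect trials);
the baseline task uses two regressors (left/right feature) of eight bins.

No intercept column is included: the data arrive as detrended percent
signal change with per-run mean ~0; r² is nevertheless computed about each
voxel's mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from ._exceptions import (DesignMatrixError, LabelingError, ParameterError,
                          SelectionError, ShapeError)
from .containers import VoxelTimeSeries
from .synthetic_data import TaskDesign, TrialEvent

logger = logging.getLogger(__name__)

__all__ = ["FIRSpec", "FIRDesign", "DeconvolutionFit",
           "attention_fir_spec", "baseline_fir_spec",
           "attention_trial_label", "baseline_trial_label",
           "build_fir_design", "filter_fir_design", "fit_fir", "compute_r2",
           "select_top_voxels"]

LONG_DELAYS = (6.1, 8.3)
SHORT_DELAYS = (1.7, 3.9)


@dataclass(frozen=True)
class FIRSpec:
    """Ordered regressor labels with a common (or per-label) bin count."""
    regressors: tuple          # tuple of (label, n_bins)
    tr: float

    def __post_init__(self):
        labels = [lab for lab, _ in self.regressors]
        if len(set(labels)) != len(labels):
            raise ParameterError("regressor labels must be unique")
        if any(n < 1 for _, n in self.regressors):
            raise ParameterError("each regressor needs at least 1 bin")

    @property
    def labels(self) -> list:
        return [lab for lab, _ in self.regressors]

    @property
    def total_columns(self) -> int:
        return sum(n for _, n in self.regressors)


@dataclass
class FIRDesign:
    """Timepoints x columns indicator matrix plus the column -> (label, bin) map."""
    matrix: np.ndarray
    column_map: list           # list of (label, bin), one per column
    spec: FIRSpec


@dataclass
class DeconvolutionFit:
    """Per-label (bins x voxels) FIR betas, the fitted series, and per-voxel r²."""
    betas: dict
    fitted: np.ndarray         # voxels x timepoints
    r2: np.ndarray | None = None
    design: FIRDesign | None = None

    def beta_matrix(self) -> np.ndarray:
        """Betas restacked to (total_columns x voxels) in design column order."""
        return np.concatenate([self.betas[lab] for lab in self.design.spec.labels])


def attention_fir_spec(tr: float = 2.2, n_bins: int = 12) -> FIRSpec:
    """Ten-regressor attention-task spec (4 long-correct + 2 short + 4 incorrect)."""
    labels = ([f"{cond}_{d}" for cond in ("attend_left", "attend_right")
               for d in LONG_DELAYS]
              + [f"correct_short_{d}" for d in SHORT_DELAYS]
              + [f"incorrect_{d}" for d in sorted(SHORT_DELAYS + LONG_DELAYS)])
    return FIRSpec(tuple((lab, n_bins) for lab in labels), tr)


def baseline_fir_spec(tr: float = 2.2, n_bins: int = 8) -> FIRSpec:
    """Two-regressor baseline-task spec (left / right feature)."""
    return FIRSpec(tuple((lab, n_bins) for lab in ("left", "right")), tr)


def attention_trial_label(trial: TrialEvent) -> str:
    """Map an attention trial onto its regressor (correctness x condition x delay)."""
    if trial.delay is None:
        raise LabelingError("attention labeling needs a delay field")
    d = trial.delay
    if not trial.correct:
        return f"incorrect_{d}"
    if d in LONG_DELAYS:
        return f"{trial.condition}_{d}"
    return f"correct_short_{d}"


def baseline_trial_label(trial: TrialEvent) -> str:
    return trial.condition


def build_fir_design(design: TaskDesign, spec: FIRSpec,
                     trial_to_label: Callable | Mapping | None = None) -> FIRDesign:
    """Stamp each trial's FIR bins into the indicator matrix.

    A trial with onset TR index k and label L (B bins) sets a 1 in L's bin
    b at row k+b, truncated at the run end; overlapping trials superpose
    (entries sum).  ``trial_to_label`` may be a callable, a mapping from
    trial index to label, or None to use the task's canonical labeler.
    """
    if trial_to_label is None:
        trial_to_label = (attention_trial_label if design.task == "attention"
                          else baseline_trial_label)
    col_start = {}
    column_map = []
    c = 0
    for lab, n_bins in spec.regressors:
        col_start[lab] = c
        column_map.extend((lab, b) for b in range(n_bins))
        c += n_bins
    n_bins_of = dict(spec.regressors)

    T = design.n_timepoints
    X = np.zeros((T, spec.total_columns))
    for i, trial in enumerate(design.trials):
        if callable(trial_to_label):
            label = trial_to_label(trial)
        else:
            label = trial_to_label[i]
        if label not in col_start:
            raise LabelingError(f"trial {i} maps to unknown label {label!r}")
        k = int(round(trial.onset / spec.tr))
        if k >= T:
            raise DesignMatrixError(f"trial {i} onset TR {k} beyond run end {T}")
        for b in range(n_bins_of[label]):
            if k + b < T:
                X[k + b, col_start[label] + b] += 1.0
    return FIRDesign(matrix=X, column_map=column_map, spec=spec)


def filter_fir_design(fir: FIRDesign, run_lengths, cutoff_hz: float = 0.01
                      ) -> FIRDesign:
    """Apply the data's detrend/high-pass to the design matrix, run by run.

    When the time series have been detrended and high-pass filtered, the
    indicator columns must receive the identical transform (standard GLM
    practice); otherwise the data's missing mean/low frequencies are
    absorbed into the betas as a negative offset and the FIR baseline loses
    its meaning.  ``run_lengths`` gives the per-run timepoint counts of the
    concatenated design.
    """
    from .preprocess import detrend_highpass  # local import: no cycle at module load

    X = fir.matrix.copy()
    if sum(run_lengths) != X.shape[0]:
        raise ShapeError("run lengths do not sum to the design's row count")
    start = 0
    for n in run_lengths:
        seg = VoxelTimeSeries(X[start:start + n].T, tr=fir.spec.tr, units="psc")
        X[start:start + n] = detrend_highpass(seg, cutoff_hz).data.T
        start += n
    return FIRDesign(matrix=X, column_map=fir.column_map, spec=fir.spec)


def fit_fir(fir: FIRDesign, ts: VoxelTimeSeries) -> DeconvolutionFit:
    """Minimum-norm least-squares FIR estimate: ``betas = pinv(X) @ data.T``."""
    if ts.units != "psc":
        raise ParameterError(f"expected psc units, got {ts.units!r}")
    X = fir.matrix
    if X.shape[0] != ts.n_timepoints:
        raise ShapeError(
            f"design rows {X.shape[0]} != timepoints {ts.n_timepoints}")
    zero_cols = np.flatnonzero(~X.any(axis=0))
    if zero_cols.size:
        logger.info("FIR design has %d all-zero column(s) (conditions with no "
                    "trials); their betas are zero by the minimum-norm solution",
                    zero_cols.size)
    B = np.linalg.pinv(X) @ ts.data.T              # columns x voxels
    fitted = (X @ B).T
    betas = {}
    c = 0
    for lab, n_bins in fir.spec.regressors:
        betas[lab] = B[c:c + n_bins]
        c += n_bins
    fit = DeconvolutionFit(betas=betas, fitted=fitted, design=fir)
    fit.r2 = compute_r2(fit, ts)
    return fit


def compute_r2(fit: DeconvolutionFit, ts: VoxelTimeSeries) -> np.ndarray:
    """Per-voxel variance explained: ``1 - SS_res / SS_tot`` about the voxel mean.

    Zero-variance voxels get r² = 0 with a logged warning.
    """
    if fit.fitted.shape != ts.data.shape:
        raise ShapeError("fit and time series shapes differ")
    resid = ts.data - fit.fitted
    ss_res = (resid ** 2).sum(axis=1)
    centered = ts.data - ts.data.mean(axis=1, keepdims=True)
    ss_tot = (centered ** 2).sum(axis=1)
    r2 = np.zeros(ts.n_voxels)
    ok = ss_tot > 0
    if (~ok).any():
        logger.warning("%d zero-variance voxel(s); r2 set to 0", int((~ok).sum()))
    r2[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    return r2


def select_top_voxels(r2: np.ndarray, k: int = 70) -> np.ndarray:
    """Indices of the k largest r² values, descending; ties by ascending index."""
    r2 = np.asarray(r2, dtype=float)
    if k > r2.size:
        raise SelectionError(f"k={k} exceeds {r2.size} available voxels")
    if k < 1:
        raise SelectionError("k must be >= 1")
    order = np.lexsort((np.arange(r2.size), -r2))
    return order[:k]
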