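"""Multivoxel pattern analysis: single-trial extraction, Fisher linear
discriminant decoding, leave-one-run-out cross-validation, cross-task
generalization, and group-level permutation inference.

The decoding currency is the :class:`TrialPatternSet`: one row per retained
trial (attention task: long-delay, correct trials by default), each row the
mean percent-signal-change over a short window of TRs anchored at trial
onset (preparation/baseline period) or stimulus onset (stimulus period).
Columns are z-scored per voxel before classification; inside
cross-validation the normalization statistics come from the training fold
only (a ``paper_mode`` flag instead normalizes the whole set once, matching
the common single-pass description).

The classifier is a two-class FLD with diagonal-loading shrinkage of the
pooled within-class covariance, ``S_lambda = (1 - lambda) S + lambda *
trace(S)/V * I``; weights ``S_lambda^{-1} (mu_pos - mu_neg)`` and bias at
the midpoint.  Group inference compares the observed group-mean accuracy to
the 95th percentile (nearest rank) of the subject-averaged label-permutation
null.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng

from ._exceptions import (ConditioningError, EmptySelectionError,
                          InsufficientDataError, MappingError, ParameterError,
                          ShapeError)
from .containers import VoxelTimeSeries
from .deconvolve import LONG_DELAYS
from .synthetic_data import TaskDesign

logger = logging.getLogger(__name__)

__all__ = ["TrialPatternSet", "FLDModel", "DecodingResult",
           "GroupPermutationResult", "extract_trial_patterns",
           "znorm_patterns", "fld_fit", "fld_predict", "cv_loro",
           "cross_decode", "subject_permutation_null",
           "group_permutation_test", "DEFAULT_LABEL_MAP"]

#: attention-task labels mapped onto the baseline-task feature labels.
DEFAULT_LABEL_MAP = {"attend_left": "left", "attend_right": "right",
                     "left": "left", "right": "right"}


@dataclass
class TrialPatternSet:
    """Trials x voxels PSC matrix with labels, run ids and a period tag."""
    patterns: np.ndarray
    labels: np.ndarray
    run_ids: np.ndarray
    period: str                 # "preparation" | "stimulus" | "baseline"
    normalized: bool = False

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.labels = np.asarray(self.labels)
        self.run_ids = np.asarray(self.run_ids)
        n = self.patterns.shape[0]
        if len(self.labels) != n or len(self.run_ids) != n:
            raise ShapeError("labels/run_ids length must equal number of trials")
        # two-class machinery; folds/subsets may transiently hold one class
        if n and len(np.unique(self.labels)) > 2:
            raise ParameterError("at most two distinct labels are supported")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def subset(self, rows) -> "TrialPatternSet":
        rows = np.asarray(rows)
        return dataclasses.replace(self, patterns=self.patterns[rows],
                                   labels=self.labels[rows],
                                   run_ids=self.run_ids[rows])

    def select_voxels(self, cols) -> "TrialPatternSet":
        return dataclasses.replace(self, patterns=self.patterns[:, np.asarray(cols)])


@dataclass
class FLDModel:
    weights: np.ndarray
    bias: float
    lam: float
    class_order: tuple          # (label_neg, label_pos), lexicographic


@dataclass
class DecodingResult:
    accuracy: float
    fold_accuracies: np.ndarray
    n_trials: int


@dataclass
class GroupPermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    threshold_95: float

    @property
    def significant(self) -> bool:
        return self.observed > self.threshold_95


# --------------------------------------------------------------------------
# extraction and normalization
# --------------------------------------------------------------------------

def extract_trial_patterns(ts: VoxelTimeSeries, design: TaskDesign,
                           period: str, window=(2, 3), *,
                           require_correct: bool = True,
                           long_delay_only: bool = True,
                           long_delays=LONG_DELAYS) -> TrialPatternSet:
    """One pattern row per retained trial: the window-mean PSC per voxel.

    Attention-task periods retain long-delay, correct trials (both toggles
    exposed); the baseline task retains every trial.  The window (inclusive
    TR offsets) anchors at trial onset for ``preparation``/``baseline`` and
    at stimulus onset for ``stimulus``.  Trials whose window extends past
    the run end are dropped with a logged count.
    """
    if ts.units != "psc":
        raise ParameterError(f"expected psc units, got {ts.units!r}")
    if period not in ("preparation", "stimulus", "baseline"):
        raise ParameterError(f"unknown period {period!r}")
    if period == "baseline" and design.task != "baseline":
        raise ParameterError("baseline period requires a baseline-task design")
    if period in ("preparation", "stimulus") and design.task != "attention":
        raise ParameterError(f"{period} period requires an attention-task design")
    start, end = window
    rows, labels, run_ids = [], [], []
    dropped = 0
    for trial in design.trials:
        if design.task == "attention":
            if long_delay_only and trial.delay not in long_delays:
                continue
            if require_correct and not trial.correct:
                continue
        anchor = (trial.stimulus_onset(design.cue_duration)
                  if period == "stimulus" else trial.onset)
        k = int(round(anchor / ts.tr))
        lo, hi = k + start, k + end
        if hi >= ts.n_timepoints:
            dropped += 1
            continue
        rows.append(ts.data[:, lo:hi + 1].mean(axis=1))
        labels.append(trial.condition)
        run_ids.append(trial.run_id if trial.run_id is not None else design.run_id)
    if dropped:
        logger.info("dropped %d trial(s) whose window exceeded the run end", dropped)
    if not rows:
        raise EmptySelectionError("no trials retained for pattern extraction")
    return TrialPatternSet(patterns=np.array(rows), labels=np.array(labels),
                           run_ids=np.array(run_ids), period=period)


def _column_stats(patterns: np.ndarray):
    mean = patterns.mean(axis=0)
    sd = patterns.std(axis=0)
    return mean, sd


def _apply_znorm(patterns: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    out = patterns - mean
    const = sd == 0
    if const.any():
        logger.info("%d constant voxel column(s) set to 0 in z-normalization",
                    int(const.sum()))
    out[:, ~const] = out[:, ~const] / sd[~const]
    out[:, const] = 0.0
    return out


def znorm_patterns(tps: TrialPatternSet) -> TrialPatternSet:
    """Z-score each voxel column across all trials (conditions pooled)."""
    if tps.normalized:
        raise ParameterError("pattern set is already normalized")
    mean, sd = _column_stats(tps.patterns)
    return dataclasses.replace(tps, patterns=_apply_znorm(tps.patterns, mean, sd),
                               normalized=True)


# --------------------------------------------------------------------------
# Fisher linear discriminant
# --------------------------------------------------------------------------

def fld_fit(train: TrialPatternSet, lam: float = 0.05) -> FLDModel:
    """Two-class shrinkage FLD; class order is fixed lexicographically."""
    if not train.normalized:
        raise ParameterError("fld_fit expects a normalized pattern set")
    if not (0.0 <= lam <= 1.0):
        raise ParameterError(f"lambda must be in [0, 1], got {lam}")
    classes = sorted(np.unique(train.labels).tolist())
    X, y = train.patterns, train.labels
    n, V = X.shape
    mus, resids = {}, []
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise InsufficientDataError(
                f"class {c!r} has {Xc.shape[0]} trial(s); need >= 2")
        mus[c] = Xc.mean(axis=0)
        resids.append(Xc - mus[c])
    R = np.concatenate(resids)
    S = (R.T @ R) / (n - 2)
    S_lam = (1.0 - lam) * S + lam * (np.trace(S) / V) * np.eye(V)
    neg, pos = classes
    delta = mus[pos] - mus[neg]
    try:
        w = np.linalg.solve(S_lam, delta)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            f"singular within-class covariance ({exc}); use lambda > 0") from exc
    if not np.isfinite(w).all():
        raise ConditioningError("non-finite FLD weights; use lambda > 0")
    bias = -0.5 * float(w @ (mus[pos] + mus[neg]))
    return FLDModel(weights=w, bias=bias, lam=lam, class_order=(neg, pos))


def fld_predict(model: FLDModel, patterns: np.ndarray) -> np.ndarray:
    """Decision rule: score > 0 -> positive class; score <= 0 -> negative class."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[1] != model.weights.size:
        raise ShapeError(
            f"pattern width {patterns.shape[1]} != weights {model.weights.size}")
    scores = patterns @ model.weights + model.bias
    neg, pos = model.class_order
    return np.where(scores > 0, pos, neg)


# --------------------------------------------------------------------------
# decoding schemes
# --------------------------------------------------------------------------

def _map_labels(labels: np.ndarray, target_labels, label_map) -> np.ndarray:
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    target = set(target_labels)
    out = []
    for lab in labels:
        mapped = lab if lab in target else label_map.get(lab)
        if mapped not in target:
            raise MappingError(f"no label correspondence for {lab!r}")
        out.append(mapped)
    return np.array(out)


def cv_loro(tps: TrialPatternSet, lam: float = 0.05, *,
            paper_mode: bool = False) -> DecodingResult:
    """Leave-one-run-out cross-validated decoding accuracy.

    Each fold trains on all other runs and tests every trial of the held-out
    run exactly once; accuracy is total correct over total tested.  Column
    z-scoring uses training-fold statistics unless ``paper_mode`` pre-
    normalizes the whole set once.
    """
    runs = np.unique(tps.run_ids)
    if runs.size < 2:
        raise ParameterError("leave-one-run-out needs >= 2 distinct runs")
    if paper_mode and not tps.normalized:
        tps = znorm_patterns(tps)
    fold_acc, fold_n = [], []
    total_correct = 0
    total_n = 0
    for r in runs:
        test_mask = tps.run_ids == r
        train = tps.subset(~test_mask)
        test = tps.subset(test_mask)
        classes, counts = np.unique(train.labels, return_counts=True)
        if classes.size < 2 or counts.min() < 2:
            logger.warning("fold run=%s skipped: insufficient training trials "
                           "per class", r)
            continue
        if not tps.normalized:
            mean, sd = _column_stats(train.patterns)
            train = dataclasses.replace(
                train, patterns=_apply_znorm(train.patterns, mean, sd),
                normalized=True)
            test = dataclasses.replace(
                test, patterns=_apply_znorm(test.patterns, mean, sd),
                normalized=True)
        model = fld_fit(train, lam)
        pred = fld_predict(model, test.patterns)
        n_correct = int((pred == test.labels).sum())
        fold_acc.append(n_correct / test.n_trials)
        fold_n.append(test.n_trials)
        total_correct += n_correct
        total_n += test.n_trials
    if not fold_acc:
        raise InsufficientDataError("all cross-validation folds were skipped")
    return DecodingResult(accuracy=total_correct / total_n,
                          fold_accuracies=np.asarray(fold_acc),
                          n_trials=total_n)


def cross_decode(train: TrialPatternSet, test: TrialPatternSet,
                 lam: float = 0.05, label_map=None) -> DecodingResult:
    """Train once on one task/period, test once on another (no folding).

    Both sets are z-normalized within themselves (if not already); test
    labels are translated into the training label space, by default
    ``attend_left <-> left``.
    """
    if train.n_voxels != test.n_voxels:
        raise ShapeError("train and test voxel counts differ")
    if not train.normalized:
        train = znorm_patterns(train)
    if not test.normalized:
        test = znorm_patterns(test)
    target = np.unique(train.labels)
    mapped = _map_labels(test.labels, target, label_map)
    model = fld_fit(train, lam)
    pred = fld_predict(model, test.patterns)
    acc = float((pred == mapped).mean())
    return DecodingResult(accuracy=acc, fold_accuracies=np.array([acc]),
                          n_trials=test.n_trials)


def subject_permutation_null(train: TrialPatternSet, *, scheme: str = "loro",
                             test: TrialPatternSet | None = None,
                             n_perm: int = 1000, lam: float = 0.05,
                             seed: int | SeedSequence = 0,
                             paper_mode: bool = False,
                             label_map=None) -> np.ndarray:
    """Null decoding accuracies from shuffled training labels.

    Each permutation shuffles the training labels uniformly (test labels
    untouched) and reruns the identical pipeline -- same normalization
    policy, shrinkage and folding.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if scheme not in ("loro", "cross"):
        raise ParameterError(f"unknown scheme {scheme!r}")
    if scheme == "cross" and test is None:
        raise ParameterError("cross scheme needs a test set")
    rng = default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = dataclasses.replace(train,
                                       labels=rng.permutation(train.labels))
        if scheme == "loro":
            null[i] = cv_loro(shuffled, lam, paper_mode=paper_mode).accuracy
        else:
            null[i] = cross_decode(shuffled, test, lam, label_map).accuracy
    return null


def group_permutation_test(observed, nulls) -> GroupPermutationResult:
    """Subject-averaged permutation inference.

    ``nulls`` is subjects x n_perm; the group null averages the subjects'
    i-th permutation accuracies, the threshold is its nearest-rank 95th
    percentile, and ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    if nulls.ndim != 2 or observed.ndim != 1:
        raise ShapeError("observed must be 1-D and nulls 2-D (subjects x perms)")
    if nulls.shape[0] != observed.size:
        raise ShapeError("one null vector per subject is required")
    group_null = nulls.mean(axis=0)
    obs = float(observed.mean())
    n_perm = group_null.size
    rank = int(np.ceil(0.95 * n_perm)) - 1
    threshold = float(np.sort(group_null)[rank])
    p = float((1 + (group_null >= obs).sum()) / (1 + n_perm))
    return GroupPermutationResult(observed=obs, null=group_null,
                                  p_value=p, threshold_95=threshold)
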