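"""Run-wise preprocessing: percent signal change, detrending, high-pass, concatenation.

Order of operations is fixed as PSC -> linear detrend -> DCT high-pass ->
(noisy-voxel removal) -> concatenation.  The high-pass is a
discrete-cosine-basis projection: DCT-II components with frequency below
the cutoff (including the mean term) are removed, which is deterministic
and free of filter edge artifacts.  Head motion correction is a documented
pass-through (:func:`motion_correct`): synthetic data carry no motion.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np


from ._exceptions import (DegenerateVoxelError, EmptySelectionError,
                          ParameterError, ShapeError)
from .containers import VoxelTimeSeries
from .synthetic_data import TaskDesign

logger = logging.getLogger(__name__)

__all__ = ["to_percent_signal_change", "detrend_highpass", "motion_correct",
           "remove_noisy_voxels", "concatenate_runs", "split_concatenated",
           "preprocess_runs"]


def motion_correct(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Pass-through stage holding the motion-correction slot in the chain."""
    return ts.with_data(ts.data, step="motion_correct(noop)")


def to_percent_signal_change(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Express each voxel as percent deviation from its own run mean.

    ``out[v, t] = 100 * (in[v, t] - mean_v) / mean_v``
    """
    if ts.units != "raw":
        raise ParameterError(f"expected raw units, got {ts.units!r}")
    means = ts.data.mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise DegenerateVoxelError(
            f"voxel(s) {bad.tolist()} have non-positive run mean; PSC undefined")
    out = 100.0 * (ts.data - means[:, None]) / means[:, None]
    return ts.with_data(out, units="psc", step="psc")


def detrend_highpass(ts: VoxelTimeSeries, cutoff_hz: float = 0.01) -> VoxelTimeSeries:
    """Remove the best-fit line and cosine components below ``cutoff_hz``.

    The confounds (constant, linear trend, and DCT-II cosines whose
    frequency ``k / (2 * T * tr)`` lies strictly below the cutoff) are
    projected out jointly, so the operation is exactly idempotent.  Output
    voxel means are ~0.
    """
    if ts.units != "psc":
        raise ParameterError(f"expected psc units, got {ts.units!r}")
    T = ts.n_timepoints
    if T < 4:
        raise ParameterError(f"need at least 4 timepoints, got {T}")
    nyquist = 1.0 / (2.0 * ts.tr)
    if cutoff_hz > nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz above Nyquist {nyquist:.4g} Hz")
    # joint confound projection: constant + linear trend + DCT-II cosines
    # below the cutoff, removed in one orthogonal projection (idempotent)
    x = np.arange(T)
    freqs = np.arange(T) / (2.0 * T * ts.tr)
    low = [k for k in range(1, T) if freqs[k] < cutoff_hz]
    C = np.column_stack([np.ones(T), x - x.mean()]
                        + [np.cos(np.pi * (x + 0.5) * k / T) for k in low])
    Q, _ = np.linalg.qr(C)
    out = ts.data - (ts.data @ Q) @ Q.T
    return ts.with_data(out, step=f"detrend_highpass({cutoff_hz})")


def remove_noisy_voxels(ts_list: list, threshold_psc: float = 10.0):
    """Drop voxels exceeding ``threshold_psc`` in magnitude anywhere in any run.

    Returns ``(filtered_ts_list, kept_indices)``; ``kept_indices`` maps the
    retained rows back to original voxel indices.
    """
    if not ts_list:
        raise ParameterError("empty run list")
    n_vox = ts_list[0].n_voxels
    for ts in ts_list:
        if ts.units != "psc":
            raise ParameterError("remove_noisy_voxels expects psc units")
        if ts.n_voxels != n_vox:
            raise ShapeError("runs disagree on voxel count")
    keep = np.ones(n_vox, dtype=bool)
    for ts in ts_list:
        keep &= (np.abs(ts.data) <= threshold_psc).all(axis=1)
    kept_indices = np.flatnonzero(keep)
    if kept_indices.size == 0:
        raise EmptySelectionError("all voxels exceeded the noise threshold")
    if kept_indices.size < n_vox:
        logger.info("removed %d noisy voxel(s) above %.3g%% signal change",
                    n_vox - kept_indices.size, threshold_psc)
    out = [ts.with_data(ts.data[kept_indices], step="remove_noisy_voxels")
           for ts in ts_list]
    return out, kept_indices


def concatenate_runs(ts_list: list, designs: list):
    """Concatenate runs along time; offset trial onsets by cumulative run durations.

    Returns a combined :class:`VoxelTimeSeries` (``run_id=-1``) and a
    combined :class:`TaskDesign` whose trials keep their originating
    ``run_id`` for cross-validation folding.
    """
    if len(ts_list) != len(designs) or not ts_list:
        raise ShapeError("need equally many (non-zero) runs and designs")
    n_vox, tr = ts_list[0].n_voxels, ts_list[0].tr
    task = designs[0].task
    for ts, d in zip(ts_list, designs):
        if ts.n_voxels != n_vox:
            raise ShapeError("runs disagree on voxel count")
        if abs(ts.tr - tr) > 1e-9 or abs(d.tr - tr) > 1e-9:
            raise ShapeError("runs disagree on TR")
        if ts.n_timepoints != d.n_timepoints:
            raise ShapeError("time series and design disagree on n_timepoints")
    data = np.concatenate([ts.data for ts in ts_list], axis=1)
    trials = []
    offset = 0.0
    for ts, d in zip(ts_list, designs):
        for trial in d.trials:
            trials.append(dataclasses.replace(
                trial, onset=trial.onset + offset,
                onset_nominal=(None if trial.onset_nominal is None
                               else trial.onset_nominal + offset),
                run_id=d.run_id))
        offset += ts.duration
    combined_ts = VoxelTimeSeries(data=data, tr=tr, run_id=-1,
                                  units=ts_list[0].units,
                                  history=list(ts_list[0].history) + ["concatenate_runs"])
    combined_design = TaskDesign(run_id=-1, task=task, trials=trials, tr=tr,
                                 n_timepoints=data.shape[1],
                                 cue_mapping=designs[0].cue_mapping)
    return combined_ts, combined_design


def split_concatenated(ts: VoxelTimeSeries, n_timepoints_list: list) -> list:
    """Inverse of the time-axis concatenation (for round-trip checks)."""
    if sum(n_timepoints_list) != ts.n_timepoints:
        raise ShapeError("segment lengths do not sum to the concatenated length")
    out, start = [], 0
    for rid, n in enumerate(n_timepoints_list):
        out.append(VoxelTimeSeries(data=ts.data[:, start:start + n], tr=ts.tr,
                                   run_id=rid, units=ts.units,
                                   history=list(ts.history) + ["split"]))
        start += n
    return out


def preprocess_runs(ts_list: list, designs: list, *, cutoff_hz: float = 0.01,
                    noise_threshold_psc: float = 10.0, keep: np.ndarray | None = None):
    """Standard chain for a list of same-task runs.

    motion pass-through -> PSC -> detrend/high-pass -> noisy-voxel removal
    (or apply a precomputed ``keep`` index, so attention and baseline runs
    can share one voxel set) -> concatenation.  Returns
    ``(combined_ts, combined_design, kept_indices)``.
    """
    proc = [detrend_highpass(to_percent_signal_change(motion_correct(ts)),
                             cutoff_hz) for ts in ts_list]
    if keep is None:
        proc, kept = remove_noisy_voxels(proc, noise_threshold_psc)
    else:
        kept = np.asarray(keep)
        proc = [ts.with_data(ts.data[kept], step="apply_voxel_subset") for ts in proc]
    combined_ts, combined_design = concatenate_runs(proc, designs)
    return combined_ts, combined_design, kept
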