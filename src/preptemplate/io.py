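"""Disk formats: BIDS-style events TSV, NIfTI / plain-matrix time series,
JSON ground-truth sidecars.

Voxels are unraveled along the first spatial axis of a 4-D NIfTI image
(shape ``(V, 1, 1, T)``), with the TR recorded in the header; a plain
whitespace-delimited matrix (voxels x timepoints) is accepted as a
text-only alternative.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._exceptions import ParameterError
from .containers import VoxelTimeSeries
from .synthetic_data import (GroundTruth, HRFParams, SimulatedSubject,
                             TaskDesign, TrialEvent)

__all__ = ["events_to_frame", "write_events_tsv", "read_events_tsv",
           "write_timeseries", "read_timeseries",
           "write_ground_truth", "read_ground_truth",
           "save_subject", "save_cohort"]


def events_to_frame(design: TaskDesign) -> pd.DataFrame:
    """Events table: onset, duration, trial_type, delay, iti, correct (+ extras)."""
    rows = []
    for t in design.trials:
        dur = design.stim_duration if t.delay is None else (
            design.cue_duration + t.delay + design.stim_duration)
        rows.append({
            "onset": t.onset, "duration": dur, "trial_type": t.condition,
            "delay": np.nan if t.delay is None else t.delay, "iti": t.iti,
            "correct": int(t.correct),
            "onset_nominal": (np.nan if t.onset_nominal is None
                              else t.onset_nominal),
            "run_id": design.run_id if t.run_id is None else t.run_id,
        })
    return pd.DataFrame(rows)


def write_events_tsv(design: TaskDesign, path) -> None:
    events_to_frame(design).to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path, task: str, tr: float, n_timepoints: int,
                    run_id: int = 0) -> TaskDesign:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    trials = []
    for _, r in df.iterrows():
        delay = None if pd.isna(r.get("delay", np.nan)) else float(r["delay"])
        nominal = r.get("onset_nominal", np.nan)
        trials.append(TrialEvent(
            onset=float(r["onset"]), condition=str(r["trial_type"]),
            iti=float(r["iti"]), delay=delay, correct=bool(int(r["correct"])),
            onset_nominal=None if pd.isna(nominal) else float(nominal),
            run_id=None if "run_id" not in df.columns else int(r["run_id"])))
    return TaskDesign(run_id=run_id, task=task, trials=trials, tr=tr,
                      n_timepoints=n_timepoints)


def write_timeseries(ts: VoxelTimeSeries, path) -> None:
    """NIfTI if the suffix says so, else a plain whitespace-delimited matrix."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(ts.data[:, None, None, :].astype(np.float64),
                              affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, ts.tr))
        nib.save(img, str(path))
    else:
        np.savetxt(path, ts.data, header=f"tr={ts.tr} units={ts.units}")


def read_timeseries(path, tr: float | None = None, run_id: int = 0,
                    units: str = "raw") -> VoxelTimeSeries:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        V, T = data.shape[0], data.shape[-1]
        data = data.reshape(V, T)
        tr_hdr = float(img.header.get_zooms()[-1])
        tr = tr_hdr if tr is None else tr
    else:
        data = np.loadtxt(path)
        if tr is None:
            with open(path) as fh:
                first = fh.readline()
            if "tr=" not in first:
                raise ParameterError("tr not given and not recorded in the file")
            tr = float(first.split("tr=")[1].split()[0])
    return VoxelTimeSeries(data=data, tr=float(tr), run_id=run_id, units=units)


def write_ground_truth(truth: GroundTruth, path) -> None:
    d = dataclasses.asdict(truth)
    for key in ("sensory_pattern", "prep_pattern"):
        d[key] = {k: np.asarray(v).tolist() for k, v in d[key].items()}
    for key in ("quadrant_map", "sensory_axis", "prep_axis"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    d["hrf_params"] = HRFParams(**d["hrf_params"])
    for key in ("sensory_pattern", "prep_pattern"):
        d[key] = {k: np.asarray(v) for k, v in d[key].items()}
    for key in ("quadrant_map", "sensory_axis", "prep_axis"):
        if d[key] is not None:
            d[key] = np.asarray(d[key])
    return GroundTruth(**d)


def save_subject(subject: SimulatedSubject, out_dir, *, nifti: bool = True) -> Path:
    """Write one subject's runs (events TSV + time series) and truth sidecar."""
    out = Path(out_dir) / f"sub-{subject.subject_id:02d}"
    out.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if nifti else ".txt"
    for task, designs, runs in (
            ("attention", subject.attention_designs, subject.attention_runs),
            ("baseline", subject.baseline_designs, subject.baseline_runs)):
        for d, ts in zip(designs, runs):
            stem = f"task-{task}_run-{d.run_id:02d}"
            write_events_tsv(d, out / f"{stem}_events.tsv")
            write_timeseries(ts, out / f"{stem}_bold{ext}")
    write_ground_truth(subject.truth, out / "ground_truth.json")
    return out


def save_cohort(subjects, out_dir, *, nifti: bool = True) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        save_subject(s, out, nifti=nifti)
    return out
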