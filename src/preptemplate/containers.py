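"""Shared in-memory containers.

The package's working currency is the run-wise voxels x timepoints matrix.
A thin dataclass wraps it with the sampling interval (TR), the run id and a
units tag, so that downstream stages can assert they receive data in the
state they expect (``raw`` scanner-like units vs percent signal change).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import ParameterError, ShapeError

__all__ = ["VoxelTimeSeries"]


@dataclass
class VoxelTimeSeries:
    """A single run's (or concatenation of runs') multivoxel time series.

    Parameters
    ----------
    data
        Array of shape ``(n_voxels, n_timepoints)``.
    tr
        Sampling interval in seconds.
    run_id
        Integer id of the originating run; ``-1`` marks a concatenation.
    units
        ``"raw"`` for scanner-like units, ``"psc"`` for percent signal
        change about the per-run voxel mean.
    history
        Names of the processing steps already applied, in order.
    """

    data: np.ndarray
    tr: float
    run_id: int = 0
    units: str = "raw"
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError(f"data must be 2-D (voxels x time), got ndim={self.data.ndim}")
        if not np.isfinite(self.data).all():
            raise ShapeError("time series contains non-finite values")
        if self.tr <= 0:
            raise ParameterError(f"tr must be positive, got {self.tr}")
        if self.units not in ("raw", "psc"):
            raise ParameterError(f"units must be 'raw' or 'psc', got {self.units!r}")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Run length in seconds."""
        return self.n_timepoints * self.tr

    def with_data(self, data: np.ndarray, *, units: str | None = None,
                  step: str | None = None) -> "VoxelTimeSeries":
        """Copy of self with new data (and optionally a new units tag)."""
        out = replace(self, data=np.asarray(data, dtype=float),
                      units=self.units if units is None else units,
                      history=list(self.history))
        if step is not None:
            out.history.append(step)
        return out
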