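"""Extension-time trajectories at constant trap separation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

__all__ = ["Trajectory", "mean_filter"]


@dataclass
class Trajectory:
    """Time series of extension and force at a fixed trap separation.

    ``time`` is a uniform grid in s with step 1/``sampling_rate``;
    ``extension`` in nm and ``force`` in pN are sampled on that grid.
    """

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    sampling_rate: float
    trap_separation: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.extension.size != n or self.force.size != n:
            raise ValueError("time, extension and force must have equal length")
        if not (np.all(np.isfinite(self.extension)) and np.all(np.isfinite(self.force))):
            raise ValueError("extension and force must be finite")
        if n >= 2:
            dt = np.diff(self.time)
            expected = 1.0 / self.sampling_rate
            if not np.allclose(dt, expected, rtol=1e-9, atol=1e-12 * expected):
                raise ValueError("time grid is not uniform at 1/sampling_rate")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return len(self) / self.sampling_rate


def mean_filter(traj: Trajectory, window: float) -> Trajectory:
    """Boxcar mean filter with decimation by the window length.

    ``window`` is in seconds and must span at least 2 samples; the output
    sampling rate is the input rate divided by the (integer) window length.
    A trailing partial window is dropped.
    """
    n_win = int(round(window * traj.sampling_rate))
    if n_win < 2:
        raise ValueError("window must span at least 2 samples")
    if n_win > len(traj):
        raise ValueError(
            f"window of {n_win} samples longer than trajectory ({len(traj)} samples)"
        )
    n_out = len(traj) // n_win
    sl = slice(0, n_out * n_win)

    def block_mean(a: np.ndarray) -> np.ndarray:
        return a[sl].reshape(n_out, n_win).mean(axis=1)

    fs_out = traj.sampling_rate / n_win
    meta = dict(traj.metadata)
    meta["mean_filter_window_s"] = n_win / traj.sampling_rate
    return Trajectory(
        time=block_mean(traj.time),
        extension=block_mean(traj.extension),
        force=block_mean(traj.force),
        sampling_rate=fs_out,
        trap_separation=traj.trap_separation,
        metadata=meta,
    )
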