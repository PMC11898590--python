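"""Shared in-memory containers for the simulation and quantification pipeline.

Array axis convention throughout the package: volumes are indexed ``[x, y, z]``
with ``x`` mediolateral, ``y`` anteroposterior and ``z`` craniocaudal, 0-based
voxel indices, isotropic spacing in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeActivityCurve:
    """Activity concentration versus time for a region (blood pool or tissue).

    ``times`` are seconds from acquisition start (frame midpoints for framed
    data, second centres for per-second data); ``values`` are concentrations in
    arbitrary activity units per voxel per second.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(self.times.copy(), np.asarray(values, dtype=float),
                                 self.label if label is None else label)


@dataclass
class HistoImageSeries:
    """Stack of 1-second-binned 3D activity histo-volumes (a DVH series).

    ``volumes`` has shape ``(n_seconds, nx, ny, nz)``; ``second_index`` gives
    the acquisition second each volume was binned from.
    """

    volumes: np.ndarray
    second_index: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes)
        self.second_index = np.asarray(self.second_index, dtype=int)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be a 4-D array (seconds, x, y, z)")
        if self.second_index.shape[0] != self.volumes.shape[0]:
            raise ValueError("one volume per second index required")
        if np.any(self.volumes < 0):
            raise ValueError("histo-volume counts must be non-negative")

    @property
    def n_seconds(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    def total_counts(self) -> float:
        return float(self.volumes.sum())


@dataclass
class DynamicFrameSeries:
    """Frame-binned dynamic volumes with contiguous half-open time windows."""

    volumes: np.ndarray
    frame_starts: np.ndarray
    frame_ends: np.ndarray
    voxel_size_mm: float
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes)
        self.frame_starts = np.asarray(self.frame_starts, dtype=float)
        self.frame_ends = np.asarray(self.frame_ends, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (frames, x, y, z)")
        n = self.volumes.shape[0]
        if self.frame_starts.shape != (n,) or self.frame_ends.shape != (n,):
            raise ValueError("frame boundaries must match the number of frames")
        if np.any(self.frame_ends <= self.frame_starts):
            raise ValueError("frames must have positive duration")
        if n > 1 and not np.allclose(self.frame_starts[1:], self.frame_ends[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.volumes.shape[0]

    @property
    def durations(self) -> np.ndarray:
        return self.frame_ends - self.frame_starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_starts + self.frame_ends)


@dataclass
class MotionTrace:
    """Per-second rigid displacement of the heart in mm on three axes.

    ``tracked`` marks seconds where the displacement is considered known; for
    ground-truth traces it is all True, for tracker output it reflects the
    acceptance threshold.
    """

    seconds: np.ndarray
    dx_mm: np.ndarray
    dy_mm: np.ndarray
    dz_mm: np.ndarray
    tracked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.seconds = np.asarray(self.seconds, dtype=int)
        self.dx_mm = np.asarray(self.dx_mm, dtype=float)
        self.dy_mm = np.asarray(self.dy_mm, dtype=float)
        self.dz_mm = np.asarray(self.dz_mm, dtype=float)
        n = self.seconds.size
        if self.tracked is None:
            self.tracked = np.ones(n, dtype=bool)
        self.tracked = np.asarray(self.tracked, dtype=bool)
        for arr in (self.dx_mm, self.dy_mm, self.dz_mm, self.tracked):
            if arr.shape != (n,):
                raise ValueError("all trace arrays must cover every acquisition second")
        if not (np.isfinite(self.dx_mm).all() and np.isfinite(self.dy_mm).all()
                and np.isfinite(self.dz_mm).all()):
            raise ValueError("displacements must be finite")

    def __len__(self) -> int:
        return self.seconds.size

    def displacement_mm(self) -> np.ndarray:
        """(n, 3) array of per-second displacements, axis order (x, y, z)."""
        return np.stack([self.dx_mm, self.dy_mm, self.dz_mm], axis=1)
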