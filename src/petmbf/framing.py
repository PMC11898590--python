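"""Dynamic framing schedules and per-second-to-frame binning.

The rest reconstruction uses 25 frames over the first 10 minutes
(1x10, 12x5, 2x10, 7x30, 2x60, 1x180 s); the stress reconstruction uses 26
frames over 10.5 minutes, identical except for an extra leading 30 s frame
acquired before the stress injection (the residual-activity reference frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DynamicFrameSeries, HistoImageSeries

_REST_DURATIONS = (10,) + (5,) * 12 + (10,) * 2 + (30,) * 7 + (60,) * 2 + (180,)
_STRESS_DURATIONS = (30,) + _REST_DURATIONS


@dataclass
class FramingSchedule:
    phase: str
    durations_s: tuple[int, ...]
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.phase == "rest":
            if len(self.durations_s) != 25 or sum(self.durations_s) != 600:
                raise ValueError("rest framing must have 25 frames summing to 600 s")
        elif self.phase == "stress":
            if len(self.durations_s) != 26 or sum(self.durations_s) != 630:
                raise ValueError("stress framing must have 26 frames summing to 630 s")
        else:
            raise ValueError("phase must be 'rest' or 'stress'")

    @property
    def n_frames(self) -> int:
        return len(self.durations_s)

    @property
    def total_seconds(self) -> int:
        return int(sum(self.durations_s))

    @property
    def frame_starts(self) -> np.ndarray:
        return self.start_offset_s + np.concatenate(
            [[0.0], np.cumsum(self.durations_s)[:-1]])

    @property
    def frame_ends(self) -> np.ndarray:
        return self.start_offset_s + np.cumsum(self.durations_s).astype(float)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_starts + self.frame_ends)


def build_framing(phase: str) -> FramingSchedule:
    """Return the fixed reconstruction framing for a phase."""
    if phase == "rest":
        return FramingSchedule("rest", _REST_DURATIONS)
    if phase == "stress":
        return FramingSchedule("stress", _STRESS_DURATIONS)
    raise ValueError("phase must be 'rest' or 'stress'")


def bin_frames(series: HistoImageSeries, schedule: FramingSchedule) -> DynamicFrameSeries:
    """Sum per-second volumes into dynamic frames (half-open [start, end))."""
    if series.n_seconds != schedule.total_seconds:
        raise ValueError("series span must equal the schedule's total duration")
    starts = schedule.frame_starts.astype(int)
    ends = schedule.frame_ends.astype(int)
    vols = np.add.reduceat(series.volumes, starts, axis=0)
    return DynamicFrameSeries(volumes=vols, frame_starts=starts.astype(float),
                              frame_ends=ends.astype(float),
                              voxel_size_mm=series.voxel_size_mm)
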