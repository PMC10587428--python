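"""Dynamic-acquisition frame schedules and region time-activity curves.

A dynamic PET acquisition is reconstructed into a sequence of contiguous (or
gapped) time frames.  The regional signal is reported as one activity
concentration per frame — the time-activity curve (TAC).  Continuous model
curves are reduced to frames by averaging over each frame interval, which is
how a reconstructed frame relates to the underlying tracer concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "default_frame_schedule",
    "fine_time_grid",
    "frame_average",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping acquisition frames in seconds post-injection."""

    frame_start_s: np.ndarray
    frame_end_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start_s, dtype=float)
        end = np.asarray(self.frame_end_s, dtype=float)
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_end_s", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("frame_start_s and frame_end_s must be equal-length 1-D arrays")
        if not np.all(end > start):
            raise ValueError("every frame must satisfy frame_end > frame_start")
        if not np.all(start[1:] >= end[:-1] - 1e-9):
            raise ValueError("frames must be ordered and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.frame_start_s.size

    @property
    def duration_s(self) -> np.ndarray:
        return self.frame_end_s - self.frame_start_s

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    @property
    def mid_s(self) -> np.ndarray:
        return 0.5 * (self.frame_start_s + self.frame_end_s)

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def span_s(self) -> float:
        return float(self.frame_end_s[-1] - self.frame_start_s[0])

    def __len__(self) -> int:
        return self.n_frames


def default_frame_schedule() -> FrameSchedule:
    """The 30-min dynamic schedule: 12 x 10 s, 6 x 30 s, 6 x 150 s, 2 x 300 s.

    26 contiguous frames spanning 0-1800 s: fine early sampling to catch the
    blood-pool first pass, coarse late frames where count rates have decayed.
    """
    durations = np.concatenate([
        np.full(12, 10.0),
        np.full(6, 30.0),
        np.full(6, 150.0),
        np.full(2, 300.0),
    ])
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return FrameSchedule(edges[:-1], edges[1:])


@dataclass
class TimeActivityCurve:
    """Activity concentration per frame for one region/subject/tracer.

    ``values`` are in ``units`` (kBq/mL by convention, SUV after
    normalisation); ``decay_corrected`` records whether physical ^11C decay
    has been removed (the conventional scanner output).
    """

    schedule: FrameSchedule
    values: np.ndarray
    units: str = "kBq/mL"
    decay_corrected: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values has shape {self.values.shape}, schedule has "
                f"{self.schedule.n_frames} frames"
            )

    def with_values(self, values: np.ndarray, **changes) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, dtype=float), **changes)

    @property
    def t_mid_min(self) -> np.ndarray:
        return self.schedule.mid_min


def fine_time_grid(schedule: FrameSchedule, step_s: float = 0.5) -> np.ndarray:
    """Uniform time grid (minutes) from 0 to the schedule end.

    The step must divide every frame boundary so frame averages are computed
    on aligned nodes; 0.5 s divides the 10/30/150/300 s frame durations.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    end = schedule.frame_end_s[-1]
    n = int(round(end / step_s))
    if not np.allclose(schedule.frame_start_s / step_s, np.round(schedule.frame_start_s / step_s)):
        raise ValueError("step_s must divide every frame boundary")
    return np.linspace(0.0, end, n + 1) / 60.0


def frame_average(t_min: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a continuous-time curve over each frame (trapezoidal)."""
    t_s = np.asarray(t_min) * 60.0
    if t_s[0] > schedule.frame_start_s[0] + 1e-9 or t_s[-1] < schedule.frame_end_s[-1] - 1e-9:
        raise ValueError("time grid does not cover the frame schedule")
    cum = np.concatenate([[0.0], cumulative_trapezoid(np.asarray(y, dtype=float), t_s)])
    lo = np.interp(schedule.frame_start_s, t_s, cum)
    hi = np.interp(schedule.frame_end_s, t_s, cum)
    return (hi - lo) / schedule.duration_s
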