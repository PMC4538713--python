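"""PET frame boundaries from navigator start times via the midpoint rule.

Frames are split at the midpoint between consecutive navigator start times,
so every instant of PET data is linked to the nearest motion sample.  The
first frame starts at the scan start, the last ends at the scan end; a
navigator outside the scan window still contributes its midpoints but its
frame is clipped to the window (and dropped, with a warning, if clipping
empties it).

Frame intervals are half-open ``[start, end)`` with the last frame closed,
so the frames tile the scan window exactly with no double counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Frame", "FrameSchedule", "compute_frames", "assign_frame"]


@dataclass(frozen=True)
class Frame:
    start_s: float
    end_s: float
    navigator_label: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered frames tiling ``[scan_start_s, scan_end_s]`` exactly."""

    frames: tuple[Frame, ...]
    scan_start_s: float
    scan_end_s: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("schedule must contain at least one frame")
        if self.frames[0].start_s != self.scan_start_s:
            raise ValueError("first frame must start at scan start")
        if self.frames[-1].end_s != self.scan_end_s:
            raise ValueError("last frame must end at scan end")
        for a, b in zip(self.frames, self.frames[1:]):
            if a.end_s != b.start_s:
                raise ValueError("frames must be contiguous")
        if any(f.end_s <= f.start_s for f in self.frames):
            raise ValueError("frames must have positive duration")

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([f.duration_s for f in self.frames])

    def to_dataframe(self) -> pd.DataFrame:
        """Schedule as a table with columns ``frame,start_s,end_s,navigator``."""
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.frames)),
                "start_s": [f.start_s for f in self.frames],
                "end_s": [f.end_s for f in self.frames],
                "navigator": [f.navigator_label for f in self.frames],
            }
        )


def compute_frames(
    nav_start_times_s,
    scan_start_s: float,
    scan_end_s: float,
    labels: list[str] | None = None,
) -> FrameSchedule:
    """Derive the frame schedule from navigator start times.

    Boundaries sit at ``(t_i + t_{i+1}) / 2`` for consecutive navigator start
    times; the first frame begins at ``scan_start_s`` and the last ends at
    ``scan_end_s``.  Frames emptied by clipping to the scan window are
    dropped with a warning.
    """
    nav = np.asarray(nav_start_times_s, dtype=float)
    if nav.size == 0:
        raise ValueError("at least one navigator start time is required")
    if nav.size > 1 and not np.all(np.diff(nav) > 0):
        raise ValueError("navigator start times must be strictly increasing")
    if not scan_start_s < scan_end_s:
        raise ValueError("scan_start_s must be < scan_end_s")
    if labels is None:
        labels = [f"nav{i + 1}" for i in range(nav.size)]
    if len(labels) != nav.size:
        raise ValueError("one label per navigator required")

    mids = (nav[:-1] + nav[1:]) / 2.0
    edges = np.concatenate([[scan_start_s], mids, [scan_end_s]])
    frames: list[Frame] = []
    for i, label in enumerate(labels):
        start = max(edges[i], scan_start_s)
        end = min(edges[i + 1], scan_end_s)
        if end <= start:
            warnings.warn(
                f"frame for navigator {label!r} is empty after clipping to the "
                f"scan window; dropped",
                stacklevel=2,
            )
            continue
        frames.append(Frame(float(start), float(end), label))
    return FrameSchedule(tuple(frames), float(scan_start_s), float(scan_end_s))


def assign_frame(time_s: float, schedule: FrameSchedule) -> int:
    """Index of the frame containing ``time_s``.

    Intervals are half-open ``[start, end)``; the last frame is closed so
    ``time_s == scan_end_s`` maps to the final frame.
    """
    if not schedule.scan_start_s <= time_s <= schedule.scan_end_s:
        raise ValueError(
            f"time {time_s} s outside scan window "
            f"[{schedule.scan_start_s}, {schedule.scan_end_s}]"
        )
    for i, f in enumerate(schedule.frames):
        if f.start_s <= time_s < f.end_s:
            return i
    return len(schedule.frames) - 1
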