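"""Dynamic-acquisition frame schedules.

A :class:`FrameSchedule` describes the contiguous time frames of a dynamic
PET acquisition in seconds post injection.  The default one-hour thoracic
protocol has 41 frames: 12 x 10 s, 12 x 20 s, 4 x 60 s, 5 x 120 s and
8 x 300 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous frame start times and durations in seconds."""

    start_s: np.ndarray
    dur_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.dur_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "dur_s", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("start_s and dur_s must be 1-D and equally long")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous (start[i+1] = start[i] + dur[i])")

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.dur_s

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.dur_s

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def dur_min(self) -> np.ndarray:
        return self.dur_s / 60.0

    # -- serialization -----------------------------------------------------
    def to_text(self, path) -> None:
        """Write a two-column (start_s, duration_s) text file."""
        np.savetxt(path, np.column_stack([self.start_s, self.dur_s]),
                   fmt="%.6g", header="start_s duration_s")

    @classmethod
    def from_text(cls, path) -> "FrameSchedule":
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] != 2:
            raise ValueError("schedule text file must have two columns (start_s, duration_s)")
        return cls(arr[:, 0], arr[:, 1])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"start_s": self.start_s.tolist(), "dur_s": self.dur_s.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "FrameSchedule":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["start_s"]), np.asarray(d["dur_s"]))

    @classmethod
    def from_durations(cls, dur_s, t0_s: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(dur_s, dtype=float)
        start = t0_s + np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)


def make_default_schedule() -> FrameSchedule:
    """The 41-frame one-hour protocol (12x10 s, 12x20 s, 4x60 s, 5x120 s, 8x300 s)."""
    dur = np.concatenate([
        np.full(12, 10.0), np.full(12, 20.0), np.full(4, 60.0),
        np.full(5, 120.0), np.full(8, 300.0),
    ])
    return FrameSchedule.from_durations(dur)
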