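"""Dynamic PET frame schedules.

The study protocol reconstructs a 60-min scan into 33 frames:
18 x 10 s, 2 x 30 s, 1 x 60 s, 2 x 120 s, 10 x 300 s (3540 s total).
The first 3 minutes (18 frames) form the "short scale"; the whole hour
is the "long scale".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "SHORT_SCALE_MIN", "LONG_SCALE_MIN"]

SHORT_SCALE_MIN = 3.0
LONG_SCALE_MIN = 60.0


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frames starting at t = 0 (seconds)."""

    starts_s: np.ndarray
    durations_s: np.ndarray
    short_scale_cutoff_min: float = SHORT_SCALE_MIN
    long_scale_cutoff_min: float = LONG_SCALE_MIN

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)
        if starts.ndim != 1 or starts.shape != durs.shape:
            raise ValueError("starts and durations must be equal-length 1-D")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if starts.size and starts[0] != 0.0:
            raise ValueError("first frame must start at 0")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The study's 33-frame hour-long schedule."""
        durs = np.concatenate(
            [
                np.full(18, 10.0),
                np.full(2, 30.0),
                np.full(1, 60.0),
                np.full(2, 120.0),
                np.full(10, 300.0),
            ]
        )
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    # -- views -----------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.starts_s.size)

    @property
    def total_s(self) -> float:
        return float(self.starts_s[-1] + self.durations_s[-1])

    @property
    def starts_min(self) -> np.ndarray:
        return self.starts_s / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return (self.starts_s + 0.5 * self.durations_s) / 60.0

    def truncate(self, cutoff_min: float) -> "FrameSchedule":
        """Keep frames that end at or before ``cutoff_min`` minutes."""
        keep = (self.starts_s + self.durations_s) <= cutoff_min * 60.0 + 1e-9
        if not np.any(keep):
            raise ValueError("cutoff removes all frames")
        return FrameSchedule(
            self.starts_s[keep],
            self.durations_s[keep],
            self.short_scale_cutoff_min,
            self.long_scale_cutoff_min,
        )

    def for_scale(self, scale: str) -> "FrameSchedule":
        if scale == "short":
            return self.truncate(self.short_scale_cutoff_min)
        if scale == "long":
            return self.truncate(self.long_scale_cutoff_min)
        raise ValueError(f"unknown scale {scale!r} (expected 'short' or 'long')")
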