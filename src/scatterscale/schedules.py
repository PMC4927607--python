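"""Dynamic frame schedules.

Two named histogramming protocols are built in, both spanning a 60-min scan:

* ``verapamil_raclopride`` — 1x15, 3x5, 3x10, 2x30, 3x60, 2x150, 2x300,
  4x600 s (20 frames)
* ``flumazenil`` — 4x15, 4x60, 2x150, 2x300, 4x600 s (16 frames)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrameSchedule", "make_frame_schedule", "PROTOCOLS"]

PROTOCOLS: dict[str, list[tuple[int, float]]] = {
    "verapamil_raclopride": [
        (1, 15), (3, 5), (3, 10), (2, 30), (3, 60), (2, 150), (2, 300), (4, 600),
    ],
    "flumazenil": [(4, 15), (4, 60), (2, 150), (2, 300), (4, 600)],
}


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping (start_s, duration_s) frames."""

    frames_s: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.frames_s:
            raise ValueError("schedule must contain at least one frame")
        prev_end = self.frames_s[0][0]
        for start, dur in self.frames_s:
            if dur <= 0:
                raise ValueError("frame durations must be positive")
            if abs(start - prev_end) > 1e-6:
                raise ValueError("frames must be contiguous and non-overlapping")
            prev_end = start + dur

    @classmethod
    def from_durations(cls, durations_s, start_s: float = 0.0) -> "FrameSchedule":
        frames = []
        t = float(start_s)
        for d in durations_s:
            frames.append((t, float(d)))
            t += float(d)
        return cls(frames_s=tuple(frames))

    @classmethod
    def from_mid_times(cls, mid_s, durations_s) -> "FrameSchedule":
        starts = np.asarray(mid_s, dtype=float) - np.asarray(durations_s) / 2.0
        return cls(
            frames_s=tuple(
                (float(s), float(d)) for s, d in zip(starts, durations_s)
            )
        )

    @property
    def n_frames(self) -> int:
        return len(self.frames_s)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames_s])

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames_s])

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def end_s(self) -> float:
        start, dur = self.frames_s[-1]
        return start + dur

    @property
    def total_duration_s(self) -> float:
        return float(self.durations_s.sum())


def make_frame_schedule(protocol: str) -> FrameSchedule:
    """Named histogramming protocol -> schedule (see module docstring)."""
    if protocol not in PROTOCOLS:
        raise ValueError(
            f"unknown protocol {protocol!r}; choose from {sorted(PROTOCOLS)}"
        )
    durations: list[float] = []
    for count, dur in PROTOCOLS[protocol]:
        durations.extend([dur] * count)
    return FrameSchedule.from_durations(durations)
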