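"""Dynamic-acquisition frame timing.

All on-disk timing is in seconds; computation elsewhere in the package is in
minutes. :class:`FrameSchedule` stores seconds and exposes minute views so the
conversion happens in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "default_schedule", "DEFAULT_FRAME_DURATIONS_S"]

#: Frame durations (seconds) of the 30-frame / 90-min dynamic brain protocol:
#: 4 x 15, 4 x 30, 3 x 60, 2 x 120, 5 x 240, 12 x 300 s.
DEFAULT_FRAME_DURATIONS_S: tuple[int, ...] = (
    (15,) * 4 + (30,) * 4 + (60,) * 3 + (120,) * 2 + (240,) * 5 + (300,) * 12
)


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start/end times of a dynamic PET acquisition (seconds).

    Frames must be strictly increasing, have positive duration, and be
    contiguous (``ends[i] == starts[i+1]``) unless ``allow_gaps`` is set.
    """

    starts_s: np.ndarray
    ends_s: np.ndarray
    allow_gaps: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        ends = np.asarray(self.ends_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "ends_s", ends)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise ValueError("starts_s and ends_s must be equal-length 1-D arrays")
        if np.any(ends <= starts):
            bad = np.nonzero(ends <= starts)[0]
            raise ValueError(f"non-positive frame durations at indices {bad.tolist()}")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(starts[1:] < ends[:-1]):
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            raise ValueError(f"overlapping frames after indices {bad.tolist()}")
        if not self.allow_gaps and np.any(starts[1:] != ends[:-1]):
            bad = np.nonzero(starts[1:] != ends[:-1])[0]
            raise ValueError(f"gaps between frames after indices {bad.tolist()}")

    @classmethod
    def from_durations(
        cls, durations_s, t0_s: float = 0.0, allow_gaps: bool = False
    ) -> "FrameSchedule":
        d = np.asarray(durations_s, dtype=float)
        ends = t0_s + np.cumsum(d)
        starts = np.concatenate(([t0_s], ends[:-1]))
        return cls(starts, ends, allow_gaps=allow_gaps)

    # -- size / views ------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(self.starts_s.size)

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends_s - self.starts_s

    @property
    def span_s(self) -> float:
        return float(self.ends_s[-1] - self.starts_s[0])

    @property
    def mid_s(self) -> np.ndarray:
        return 0.5 * (self.starts_s + self.ends_s)

    # minute views (computation units)

    @property
    def starts_min(self) -> np.ndarray:
        return self.starts_s / 60.0

    @property
    def ends_min(self) -> np.ndarray:
        return self.ends_s / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    def __eq__(self, other) -> bool:  # dataclass eq breaks on arrays
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.starts_s.shape == other.starts_s.shape
            and bool(np.all(self.starts_s == other.starts_s))
            and bool(np.all(self.ends_s == other.ends_s))
        )

    def __hash__(self) -> int:
        return hash((self.starts_s.tobytes(), self.ends_s.tobytes()))


def default_schedule() -> FrameSchedule:
    """The 30-frame, 90-min dynamic schedule (0–5400 s)."""
    return FrameSchedule.from_durations(DEFAULT_FRAME_DURATIONS_S)
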