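"""Static-window SUVR quantification.

A standardized uptake value ratio (SUVR) is the mean activity of a target
region over a late static window divided by the reference-region mean over
the same window.  Injected dose and body mass cancel in the ratio, so
"summed" static images are computed as duration-weighted means (equivalent to
sums up to a constant that cancels).

The five canonical 20-min windows start at 30, 40, 50, 60 and 70 min
post-injection and align exactly with the 300-s frame grid of the default
schedule, so strict (no frame splitting) window/frame mapping is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import TimeActivityCurve
from .schedule import FrameSchedule

__all__ = [
    "SuvrWindow",
    "CANONICAL_WINDOWS",
    "window_frames",
    "static_mean",
    "compute_suvr",
    "suvr_table",
]


@dataclass(frozen=True)
class SuvrWindow:
    """A static acquisition window [start, end) in minutes post-injection."""

    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if self.end_min <= self.start_min:
            raise ValueError("window end must exceed start")

    @property
    def label(self) -> str:
        return f"{self.start_min:g}-{self.end_min:g}"


#: The five canonical 20-min windows, 30-50 ... 70-90 min post-injection.
CANONICAL_WINDOWS: tuple[SuvrWindow, ...] = tuple(
    SuvrWindow(start, start + 20.0) for start in (30.0, 40.0, 50.0, 60.0, 70.0)
)


def window_frames(
    schedule: FrameSchedule, window: SuvrWindow, lenient: bool = False
) -> np.ndarray:
    """Indices (0-based) of frames fully contained in the window.

    In strict mode (default) a window boundary that splits a frame is an
    error; ``lenient`` instead keeps any frame overlapping the window (its
    fractional coverage is handled by :func:`static_mean`).  The canonical
    five windows never split frames of the default schedule.
    """
    start_s = window.start_min * 60.0
    end_s = window.end_min * 60.0
    if start_s < schedule.starts_s[0] or end_s > schedule.ends_s[-1]:
        raise ValueError(f"window {window.label} extends beyond the schedule span")
    inside = (schedule.starts_s >= start_s) & (schedule.ends_s <= end_s)
    overlapping = (schedule.ends_s > start_s) & (schedule.starts_s < end_s)
    if not lenient and np.any(overlapping & ~inside):
        bad = np.nonzero(overlapping & ~inside)[0]
        raise ValueError(
            f"window {window.label} splits frame(s) {bad.tolist()}; "
            "use lenient mode for fractional weighting"
        )
    idx = np.nonzero(overlapping if lenient else inside)[0]
    if idx.size == 0:
        raise ValueError(f"window {window.label} selects no frames")
    return idx


def static_mean(
    data, window: SuvrWindow, schedule: FrameSchedule | None = None, lenient: bool = False
):
    """Duration-weighted mean activity over a static window.

    ``data`` is a TimeActivityCurve (returns a float) or a 4-D image array of
    shape (..., n_frames) with an explicit ``schedule`` (returns a 3-D array).
    In lenient mode, partially covered frames are weighted by their overlap.
    """
    if isinstance(data, TimeActivityCurve):
        schedule = data.schedule
        values = data.activity
    else:
        if schedule is None:
            raise ValueError("an image needs an explicit schedule")
        values = np.asarray(data, dtype=float)
        if values.shape[-1] != schedule.n_frames:
            raise ValueError("last image axis must match the schedule's frame count")
    idx = window_frames(schedule, window, lenient=lenient)
    start_s = window.start_min * 60.0
    end_s = window.end_min * 60.0
    overlap = np.minimum(schedule.ends_s[idx], end_s) - np.maximum(
        schedule.starts_s[idx], start_s
    )
    weights = overlap / overlap.sum()
    return values[..., idx] @ weights


def compute_suvr(target_mean, reference_mean: float):
    """SUVR = target window mean / reference window mean."""
    if np.any(np.asarray(reference_mean) <= 0):
        raise ValueError("reference window mean must be positive")
    return target_mean / reference_mean


def suvr_table(
    cohort_tacs: dict,
    windows=CANONICAL_WINDOWS,
    reference_region: str = "cerebellum",
    roi_list=None,
) -> pd.DataFrame:
    """Per-subject region x window SUVR table (long format).

    ``cohort_tacs`` maps subject_id -> {region: TimeActivityCurve}; column
    (window) order is fixed to the order of ``windows``.
    """
    rows = []
    for sid in sorted(cohort_tacs):
        regions = cohort_tacs[sid]
        if reference_region not in regions:
            raise ValueError(f"subject {sid} has no reference TAC ({reference_region})")
        reference = regions[reference_region]
        ref_means = {w.label: static_mean(reference, w) for w in windows}
        wanted = roi_list if roi_list is not None else sorted(
            r for r in regions if r != reference_region
        )
        for region in wanted:
            if region not in regions:
                raise ValueError(f"subject {sid} is missing region {region}")
            for w in windows:
                rows.append(
                    dict(
                        subject_id=sid,
                        region=region,
                        window=w.label,
                        suvr=float(
                            compute_suvr(static_mean(regions[region], w), ref_means[w.label])
                        ),
                    )
                )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["window"] = pd.Categorical(
            df["window"], categories=[w.label for w in windows], ordered=True
        )
    return df
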