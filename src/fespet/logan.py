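"""Reference-tissue Logan graphical analysis.

For a reversible tracer, plotting

    y(t) = int_0^t C_T dtau / C_T(t)
    x(t) = [ int_0^t C_ref dtau + C_ref(t)/k2' ] / C_T(t)

becomes linear after an equilibration time t*, with slope equal to the
distribution volume ratio DVR = Vt / Vt'; the non-displaceable binding
potential is BPnd = DVR - 1.  The k2' term corrects for slow reference-region
efflux and is omitted by default (reference-TAC-only transform).

Data exist only as framed averages, so cumulative integrals are rectangular
(frame value x duration) and frame midpoints serve as the time coordinates.
Points where the target frame value is non-positive (possible under heavy
noise) are dropped rather than clamped, to avoid truncation bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .kinetics import TimeActivityCurve
from .schedule import FrameSchedule

__all__ = [
    "LoganFit",
    "LoganPoints",
    "BPndMap",
    "LoganReferenceModel",
    "cumulative_integral",
    "logan_transform",
    "fit_logan",
    "select_t_star",
    "parametric_bpnd",
    "roi_dvr_table",
    "DEFAULT_T_STAR_MIN",
]

#: Default equilibration time: the start of the twelve 300-s frames, aligning
#: the kinetic fit window with the earliest static window studied.
DEFAULT_T_STAR_MIN = 30.0


@dataclass(frozen=True)
class LoganFit:
    """Result of a reference-tissue Logan fit."""

    dvr: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float
    used_k2prime: float | None = None

    @property
    def bpnd(self) -> float:
        """Non-displaceable binding potential; DVR = 1 + BPnd by identity."""
        return self.dvr - 1.0


@dataclass(frozen=True)
class LoganPoints:
    """Transformed (x, y) Logan coordinates at frame midpoints (min)."""

    t_mid: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n_dropped: int = 0


@dataclass(frozen=True)
class BPndMap:
    """Voxelwise binding-potential map with the non-binding voxels masked.

    ``bpnd`` carries NaN at masked-out voxels; ``mask`` is True where a voxel
    was retained (successful fit with BPnd > 0).
    """

    bpnd: np.ndarray
    mask: np.ndarray

    def roi_mean_dvr(self, labels: np.ndarray, label: int) -> float:
        """Mean DVR (1 + BPnd) over retained voxels of one labelled ROI."""
        sel = (labels == label) & self.mask
        if not np.any(sel):
            return float("nan")
        return float(np.mean(1.0 + self.bpnd[sel]))


def cumulative_integral(tac: TimeActivityCurve, at: str = "end") -> np.ndarray:
    """Cumulative time integral of a framed TAC (kBq/mL*min).

    Each frame value is treated as the frame's mean, so the increment over a
    frame is value x duration; if the schedule starts after t = 0 the activity
    is assumed to build up linearly from zero over the gap.  ``at`` selects
    evaluation at frame ``"end"`` (default) or frame ``"mid"`` points.
    """
    sched = tac.schedule
    dt = sched.durations_min
    increments = tac.activity * dt
    lead_in = 0.0
    if sched.starts_min[0] > 0:
        # linear build-up from zero to the first frame value
        lead_in = 0.5 * tac.activity[0] * sched.starts_min[0]
    at_end = lead_in + np.cumsum(increments)
    if at == "end":
        return at_end
    if at == "mid":
        at_start = at_end - increments
        return at_start + tac.activity * 0.5 * dt
    raise ValueError("at must be 'end' or 'mid'")


def logan_transform(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    k2prime: float | None = None,
) -> LoganPoints:
    """Transform a target/reference TAC pair into Logan (x, y) coordinates."""
    if target.schedule != reference.schedule:
        raise ValueError("target and reference must share one frame schedule")
    if k2prime is not None and k2prime <= 0:
        raise ValueError("k2prime must be positive when supplied")
    t_mid = target.schedule.mid_min
    int_t = cumulative_integral(target, at="mid")
    int_r = cumulative_integral(reference, at="mid")
    ct = target.activity
    valid = ct > 0
    n_dropped = int(np.sum(~valid))
    # leading pre-arrival frames (before any activity) are expected; only
    # warn when frames are lost after tracer arrival (heavy noise)
    first_pos = int(np.argmax(valid)) if valid.any() else valid.size
    if np.any(~valid[first_pos:]):
        warnings.warn(
            f"{int(np.sum(~valid[first_pos:]))} frame(s) with non-positive "
            "target activity excluded from the Logan transform",
            stacklevel=2,
        )
    num_x = int_r if k2prime is None else int_r + reference.activity / k2prime
    return LoganPoints(
        t_mid=t_mid[valid],
        x=num_x[valid] / ct[valid],
        y=int_t[valid] / ct[valid],
        n_dropped=n_dropped,
    )


def fit_logan(
    points: LoganPoints,
    t_star: float = DEFAULT_T_STAR_MIN,
    weights: np.ndarray | None = None,
    used_k2prime: float | None = None,
) -> LoganFit:
    """Ordinary least squares of y on x restricted to midpoints > t_star."""
    late = points.t_mid > t_star
    n = int(np.sum(late))
    if n < 3:
        raise ValueError(f"need >= 3 points after t* = {t_star} min, have {n}")
    x = points.x[late]
    y = points.y[late]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)[late]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in Logan x coordinate")
    wsum = w.sum()
    xm = (w * x).sum() / wsum
    ym = (w * y).sum() / wsum
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sst = (w * (y - ym) ** 2).sum()
    r2 = 1.0 if sst == 0 else max(0.0, min(1.0, 1.0 - (w * resid**2).sum() / sst))
    return LoganFit(
        dvr=float(slope),
        intercept=float(intercept),
        t_star=float(t_star),
        n_points=n,
        r_squared=float(r2),
        used_k2prime=used_k2prime,
    )


def select_t_star(points: LoganPoints, max_rel_deviation: float = 0.10) -> float:
    """Linearity-based t* selection.

    Returns the smallest midpoint such that a regression on all points from
    that midpoint onward leaves every one of them within ``max_rel_deviation``
    relative deviation; falls back to 30 min (with a warning) if the
    criterion is never met.
    """
    if points.t_mid.size < 4:
        raise ValueError("need >= 4 points to select t*")
    order = np.argsort(points.t_mid)
    t = points.t_mid[order]
    x = points.x[order]
    y = points.y[order]
    for i in range(t.size - 2):
        xs, ys = x[i:], y[i:]
        if np.ptp(xs) == 0:
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = intercept + slope * xs
        denom = np.where(np.abs(pred) > 0, np.abs(pred), np.inf)
        if np.max(np.abs(ys - pred) / denom) <= max_rel_deviation:
            return float(t[i])
    warnings.warn(
        "Logan linearity criterion never met; falling back to t* = 30 min",
        stacklevel=2,
    )
    return DEFAULT_T_STAR_MIN


class LoganReferenceModel(BaseEstimator):
    """Reference-tissue Logan quantifier in estimator form.

    Parameters
    ----------
    t_star : float or "auto"
        Equilibration time (min); points with midpoint > t_star enter the
        fit.  "auto" uses the linearity criterion of :func:`select_t_star`.
    k2prime : float, optional
        Reference-region efflux constant (1/min); when given, the reference
        term of the transform includes C_ref/k2'.
    weight_by_duration : bool
        Weight the regression by frame duration instead of OLS.

    Attributes (after fit)
    ----------------------
    dvr_, bpnd_, intercept_, r_squared_, n_points_, t_star_ : floats/int
    fit_ : LoganFit
    """

    def __init__(self, t_star=DEFAULT_T_STAR_MIN, k2prime=None, weight_by_duration=False):
        self.t_star = t_star
        self.k2prime = k2prime
        self.weight_by_duration = weight_by_duration

    def fit(self, target: TimeActivityCurve, reference: TimeActivityCurve):
        points = logan_transform(target, reference, self.k2prime)
        t_star = (
            select_t_star(points) if self.t_star == "auto" else float(self.t_star)
        )
        weights = None
        if self.weight_by_duration:
            durations = target.schedule.durations_min
            weights = durations[target.activity > 0]
        result = fit_logan(points, t_star, weights=weights, used_k2prime=self.k2prime)
        self.fit_ = result
        self.points_ = points
        self.dvr_ = result.dvr
        self.bpnd_ = result.bpnd
        self.intercept_ = result.intercept
        self.r_squared_ = result.r_squared
        self.n_points_ = result.n_points
        self.t_star_ = result.t_star
        return self


def parametric_bpnd(
    image4d: np.ndarray,
    reference: TimeActivityCurve,
    schedule: FrameSchedule | None = None,
    t_star: float = DEFAULT_T_STAR_MIN,
    k2prime: float | None = None,
) -> BPndMap:
    """Voxelwise Logan BPnd map; voxels with BPnd <= 0 or failed fits masked.

    ``image4d`` has shape (nx, ny, nz, n_frames) matching the reference TAC's
    schedule (or an explicit ``schedule``).
    """
    schedule = schedule or reference.schedule
    if schedule != reference.schedule:
        raise ValueError("schedule does not match the reference TAC")
    if image4d.shape[-1] != schedule.n_frames:
        raise ValueError(
            f"image has {image4d.shape[-1]} frames, schedule has {schedule.n_frames}"
        )
    spatial = image4d.shape[:-1]
    flat = image4d.reshape(-1, schedule.n_frames)
    bpnd = np.full(flat.shape[0], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(flat.shape[0]):
            voxel = TimeActivityCurve(schedule, flat[i], "voxel")
            try:
                points = logan_transform(voxel, reference, k2prime)
                fit = fit_logan(points, t_star, used_k2prime=k2prime)
            except ValueError:
                continue
            bpnd[i] = fit.bpnd
    bpnd = bpnd.reshape(spatial)
    mask = np.isfinite(bpnd) & (bpnd > 0)
    bpnd = np.where(mask, bpnd, np.nan)
    return BPndMap(bpnd=bpnd, mask=mask)


def roi_dvr_table(
    cohort_tacs: dict,
    roi_list=None,
    t_star: float = DEFAULT_T_STAR_MIN,
    reference_region: str = "cerebellum",
    k2prime: float | None = None,
) -> pd.DataFrame:
    """Per-subject, per-region Logan DVR table.

    ``cohort_tacs`` maps subject_id -> {region: TimeActivityCurve}, each
    subject including the reference region.
    """
    rows = []
    for sid in sorted(cohort_tacs):
        regions = cohort_tacs[sid]
        if reference_region not in regions:
            raise ValueError(f"subject {sid} has no reference TAC ({reference_region})")
        reference = regions[reference_region]
        wanted = roi_list if roi_list is not None else sorted(
            r for r in regions if r != reference_region
        )
        for region in wanted:
            model = LoganReferenceModel(t_star=t_star, k2prime=k2prime).fit(
                regions[region], reference
            )
            rows.append(
                dict(
                    subject_id=sid,
                    region=region,
                    dvr=model.dvr_,
                    bpnd=model.bpnd_,
                    t_star=model.t_star_,
                    n_points=model.n_points_,
                    r_squared=model.r_squared_,
                )
            )
    return pd.DataFrame(rows)
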