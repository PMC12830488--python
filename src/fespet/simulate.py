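"""Synthetic dynamic-PET data with the statistical structure of a midlife
women's estrogen-receptor imaging study.

The cohort generator draws, for each subject and region, a true distribution
volume ratio (DVR) from a group-specific normal distribution, back-solves the
two-tissue rate constants so that the target-to-reference Vt ratio equals the
drawn DVR, simulates framed noisy time-activity curves, and attaches
covariates (age, SHBG, education) and cognitive scores generated with negative
slopes on limbic/frontal binding.  A truth table of drawn DVRs and rate
constants is returned for recovery tests.

Default design values reproduce the study conditions: three menopause groups
of n = 18/18/19, a 36% POST-vs-PRE elevation of mean pituitary binding, and
per-region between-subject spreads sized so the POST-vs-PRE standardized
differences fall in the bands reported for this tracer (large for pituitary,
limbic and frontal regions; small for caudate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import (
    CompartmentParams,
    InputFunctionParams,
    TimeActivityCurve,
    frame_average,
    solve_tissue_curve,
    tissue_curve,
)
from .schedule import FrameSchedule, default_schedule

__all__ = [
    "F18_DECAY_CONST_PER_MIN",
    "REFERENCE_REGION",
    "GROUPS",
    "RegionEffect",
    "CognitionDesign",
    "CohortDesign",
    "Cohort",
    "add_noise",
    "kinetics_for_dvr",
    "simulate_cohort",
    "simulate_voxel_image",
    "default_cohort_design",
    "selection_validation_design",
]

#: Physical decay constant of F-18, ln(2)/109.77 min.
F18_DECAY_CONST_PER_MIN = math.log(2.0) / 109.77

REFERENCE_REGION = "cerebellum"
GROUPS = ("PRE", "PERI", "POST")

#: Reference-tissue kinetics: fixed one-tissue model across subjects
#: (the reference region was selected for uptake invariant to menopause
#: status, so a single parameter set is the appropriate emulation).
REFERENCE_KINETICS = CompartmentParams(K1=0.20, k2=0.20, k3=0.0, k4=0.0, vb=0.05)

#: k4 used for all binding regions; k3 is solved from the drawn DVR.
TARGET_K4 = 0.08


def kinetics_for_dvr(dvr: float, reference: CompartmentParams = REFERENCE_KINETICS,
                     k4: float = TARGET_K4, vb: float = 0.05) -> CompartmentParams:
    """Back-solve target kinetics so that target Vt / reference Vt = ``dvr``.

    K1 and k2 are held at the reference values (constant delivery), and only
    the binding rate k3 varies: with K1/k2 shared, Vt/Vt' = 1 + k3/k4, so
    k3 = k4 * (dvr - 1).  DVR differences therefore reflect receptor binding,
    not perfusion.
    """
    if dvr < 1:
        raise ValueError("dvr must be >= 1 for a binding region")
    k3 = k4 * (dvr - 1.0)
    if k3 == 0:
        return CompartmentParams(K1=reference.K1, k2=reference.k2, k3=0.0, k4=0.0, vb=vb)
    return CompartmentParams(K1=reference.K1, k2=reference.k2, k3=k3, k4=k4, vb=vb)


def add_noise(
    tac: TimeActivityCurve,
    noise_scale: float,
    seed=None,
    late_noise_slope: float = 0.0,
) -> TimeActivityCurve:
    """Add frame-wise Gaussian noise emulating count statistics.

    The count-statistics component of frame i has standard deviation

        noise_scale * sqrt(max(a_i, 0) * exp(lambda_phys * t_mid_i) / dt_i),

    with lambda_phys the F-18 decay constant: decay-corrected late frames are
    reconstructed from fewer true counts, so their noise grows with the decay
    factor and shrinks with frame duration.  ``late_noise_slope`` adds an
    independent multiplicative component with fractional SD

        late_noise_slope * max(0, t_mid - 30) / 60

    (i.e. the slope is the fractional SD reached at 90 min), emulating the
    degradation that accumulates late in long scans — subject motion and
    residual misregistration sample proportionally wrong activity; it is 0
    by default.  The two Gaussian components add in quadrature.

    ``seed`` may be an int or a numpy Generator.  noise_scale = 0 with
    late_noise_slope = 0 returns the input unchanged.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if noise_scale == 0 and not late_noise_slope:
        return tac
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t_mid = tac.schedule.mid_min
    dt = tac.schedule.durations_min
    var = noise_scale**2 * (
        np.maximum(tac.activity, 0.0) * np.exp(F18_DECAY_CONST_PER_MIN * t_mid) / dt
    )
    if late_noise_slope:
        frac = late_noise_slope * np.maximum(0.0, t_mid - 30.0) / 60.0
        var = var + (frac * tac.activity) ** 2
    return tac.with_activity(tac.activity + rng.normal(0.0, 1.0, len(var)) * np.sqrt(var))


@dataclass(frozen=True)
class RegionEffect:
    """Group means and between-subject SD of true DVR for one region."""

    mean_pre: float
    mean_peri: float
    mean_post: float
    sd: float

    def __post_init__(self) -> None:
        if min(self.mean_pre, self.mean_peri, self.mean_post) < 1:
            raise ValueError("mean true DVR must be >= 1")
        if self.sd <= 0:
            raise ValueError("between-subject SD must be > 0")

    def mean_for(self, group: str) -> float:
        return {"PRE": self.mean_pre, "PERI": self.mean_peri, "POST": self.mean_post}[group]


@dataclass(frozen=True)
class CognitionDesign:
    """Linear generative model for cognitive scores.

    Scores are generated on a standardized scale as

        score = slope * z(true binding in driver region) + age_slope * z(age) + noise,

    with negative slopes for the memory/global outcomes so that higher
    limbic binding predicts lower performance.
    """

    driver_region: str = "hippocampus"
    slopes: dict = field(
        default_factory=lambda: {
            "memory_immediate": -0.40,
            "memory_delayed": -0.45,
            "global_cognition": -0.40,
        }
    )
    age_slope: float = -0.15
    noise_sd: float = 0.93


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic cohort; the defaults are the study conditions."""

    n_per_group: dict = field(default_factory=lambda: {"PRE": 18, "PERI": 18, "POST": 19})
    regions: dict = field(default_factory=dict)  # region -> RegionEffect
    post_vs_pre_ratio: float = 1.36  # pituitary mean elevation, POST vs PRE
    #: shared between-region correlation of a subject's true binding levels
    binding_correlation: float = 0.6
    cognition: CognitionDesign = field(default_factory=CognitionDesign)
    noise_scale: float = 0.1
    late_noise_slope: float = 0.0
    age_mean_by_group: dict = field(
        default_factory=lambda: {"PRE": 46.0, "PERI": 50.0, "POST": 56.0}
    )
    age_sd: float = 4.0
    shbg_log_mean: float = math.log(60.0)
    shbg_log_sd: float = 0.4
    education_mean: float = 17.0
    education_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g in GROUPS:
            if self.n_per_group.get(g, 0) < 2:
                raise ValueError("each group needs n >= 2")
        if not (0 <= self.binding_correlation < 1):
            raise ValueError("binding_correlation must be in [0, 1)")

    def with_seed(self, seed: int) -> "CohortDesign":
        return replace(self, seed=seed)


def _default_regions() -> dict:
    """Per-region group means / SDs of true DVR.

    Pituitary carries the 36% POST-vs-PRE elevation; exploratory regions carry
    the smaller group effects and spreads that put their standardized POST-PRE
    differences in the reported bands (large for limbic/frontal/posterior
    cingulate, medium for hypothalamus/thalamus, small for caudate).
    """
    return {
        "pituitary": RegionEffect(1.50, 1.77, 2.04, 0.45),
        "amygdala": RegionEffect(1.25, 1.32, 1.40, 0.18),
        "caudate": RegionEffect(1.15, 1.17, 1.20, 0.15),
        "hippocampus": RegionEffect(1.30, 1.38, 1.46, 0.18),
        "hypothalamus": RegionEffect(1.35, 1.40, 1.46, 0.22),
        "inferior_frontal": RegionEffect(1.20, 1.28, 1.36, 0.16),
        "middle_frontal": RegionEffect(1.20, 1.27, 1.35, 0.16),
        "posterior_cingulate": RegionEffect(1.25, 1.34, 1.44, 0.16),
        "thalamus": RegionEffect(1.40, 1.45, 1.51, 0.17),
    }


def default_cohort_design(seed: int = 0, **overrides) -> CohortDesign:
    """The study-conditions design: n = 18/18/19, nine regions, 36% pituitary
    POST/PRE elevation, moderate frame noise."""
    kwargs = dict(regions=_default_regions(), seed=seed)
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


def selection_validation_design(seed: int = 0, sd_scale: float = 1.0, **overrides) -> CohortDesign:
    """Design for the window-selection validation battery.

    Identical to the default design except that frame noise is larger and
    the static-window images carry degradation noise that grows with time
    after 30 min (``late_noise_slope``): statically summed late images are
    reconstructed and registered independently of the motion-corrected
    dynamic series, and the accumulated motion/misregistration error grows
    over a long scan.  Under this design the DVR-SUVR agreement is genuinely
    highest in the 30-50 min window and declines with window start — the
    regime the selection procedures are meant to detect.
    """
    regions = {
        name: replace(eff, sd=eff.sd * sd_scale)
        for name, eff in _default_regions().items()
    }
    kwargs = dict(regions=regions, noise_scale=0.35, late_noise_slope=0.55, seed=seed)
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


@dataclass
class Cohort:
    """A simulated cohort: subject table, per-subject TACs, and ground truth.

    ``tacs`` is the motion-corrected dynamic series (count-statistics noise
    only) used for kinetic quantification.  ``static_tacs`` is the series
    backing the statically summed window images; when the design includes
    late-scan degradation (``late_noise_slope > 0``) it carries that extra
    noise, independent of the dynamic series, otherwise it is the same
    object as ``tacs``.
    """

    design: CohortDesign
    schedule: FrameSchedule
    subjects: pd.DataFrame  # subject_id, group, age_years, shbg_nmol_L, ...
    tacs: dict  # subject_id -> {region: TimeActivityCurve}, incl. reference
    truth: pd.DataFrame  # subject_id, region, true_dvr, K1, k2, k3, k4
    static_tacs: dict = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.static_tacs is None:
            self.static_tacs = self.tacs

    @property
    def regions(self) -> list:
        return sorted(self.design.regions)


def simulate_cohort(
    design: CohortDesign,
    schedule: FrameSchedule | None = None,
    aif: InputFunctionParams | None = None,
) -> Cohort:
    """Simulate a full cohort under ``design``; fully determined by its seed."""
    schedule = schedule or default_schedule()
    aif = aif or InputFunctionParams()
    rng = np.random.default_rng(design.seed)
    regions = sorted(design.regions)
    rho = design.binding_correlation

    subject_rows = []
    truth_rows = []
    tacs: dict[str, dict[str, TimeActivityCurve]] = {}
    static_tacs: dict[str, dict[str, TimeActivityCurve]] = {}
    degraded_statics = design.late_noise_slope > 0
    flags: list[str] = []

    ref_frames = frame_average(
        tissue_curve(aif, REFERENCE_KINETICS), schedule, REFERENCE_REGION
    )

    idx = 0
    for group in GROUPS:
        for _ in range(design.n_per_group[group]):
            sid = f"S{idx:03d}"
            idx += 1
            shared = rng.normal()  # subject-level binding factor
            z_by_region = {}
            subj_tacs: dict[str, TimeActivityCurve] = {}
            subj_static: dict[str, TimeActivityCurve] = {}
            for region in regions:
                eff = design.regions[region]
                z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * rng.normal()
                z_by_region[region] = z
                dvr = eff.mean_for(group) + eff.sd * z
                if dvr < 1.0:
                    dvr = 1.0
                    flags.append(f"{sid}/{region}: drawn DVR < 1 truncated to 1")
                kin = kinetics_for_dvr(dvr)
                clean = frame_average(tissue_curve(aif, kin), schedule, region)
                subj_tacs[region] = add_noise(clean, design.noise_scale, rng)
                if degraded_statics:
                    subj_static[region] = add_noise(
                        clean, design.noise_scale, rng, design.late_noise_slope
                    )
                truth_rows.append(
                    dict(subject_id=sid, region=region, true_dvr=dvr,
                         K1=kin.K1, k2=kin.k2, k3=kin.k3, k4=kin.k4)
                )
            subj_tacs[REFERENCE_REGION] = add_noise(ref_frames, design.noise_scale, rng)
            tacs[sid] = subj_tacs
            if degraded_statics:
                subj_static[REFERENCE_REGION] = add_noise(
                    ref_frames, design.noise_scale, rng, design.late_noise_slope
                )
                static_tacs[sid] = subj_static

            age = float(
                np.clip(rng.normal(design.age_mean_by_group[group], design.age_sd), 40, 65)
            )
            shbg = float(rng.lognormal(design.shbg_log_mean, design.shbg_log_sd))
            edu = float(np.clip(rng.normal(design.education_mean, design.education_sd), 12, 22))
            cog = design.cognition
            z_driver = z_by_region.get(cog.driver_region, 0.0)
            z_age = (age - 50.0) / 6.0
            scores = {
                name: slope * z_driver + cog.age_slope * z_age + cog.noise_sd * rng.normal()
                for name, slope in cog.slopes.items()
            }
            subject_rows.append(
                dict(subject_id=sid, group=group, age_years=age, shbg_nmol_L=shbg,
                     education_years=edu, **scores)
            )

    subjects = pd.DataFrame(subject_rows)
    truth = pd.DataFrame(truth_rows)
    return Cohort(design=design, schedule=schedule, subjects=subjects,
                  tacs=tacs, truth=truth,
                  static_tacs=static_tacs if degraded_statics else None,
                  flags=flags)


def simulate_voxel_image(
    grid_shape: tuple,
    kin_map: dict,
    schedule: FrameSchedule | None = None,
    noise_scale: float = 0.0,
    seed: int = 0,
    aif: InputFunctionParams | None = None,
):
    """Simulate a small labelled 4-D voxel image.

    ``kin_map`` maps region name -> CompartmentParams.  Regions are laid out
    as contiguous slabs along the first axis and emitted as an
    integer-labelled mask; unlabelled voxels (when the slab division leaves a
    remainder) carry the reference kinetics, label 0.

    Returns (image4d, labels, label_names) with image4d of shape
    grid_shape + (n_frames,), labels an int array of grid_shape, and
    label_names mapping label value -> region name.
    """
    schedule = schedule or default_schedule()
    aif = aif or InputFunctionParams()
    if int(np.prod(grid_shape)) > 16**3:
        raise ValueError("voxel grids are limited to 16^3 voxels")
    rng = np.random.default_rng(seed)
    regions = list(kin_map)
    labels = np.zeros(grid_shape, dtype=np.int16)
    nx = grid_shape[0]
    bounds = np.linspace(0, nx, len(regions) + 1).astype(int)
    label_names = {0: REFERENCE_REGION}
    region_tac = {}
    for i, region in enumerate(regions):
        lab = i + 1
        labels[bounds[i]:bounds[i + 1], ...] = lab
        label_names[lab] = region
        region_tac[lab] = frame_average(tissue_curve(aif, kin_map[region]), schedule, region)
    region_tac[0] = frame_average(tissue_curve(aif, REFERENCE_KINETICS), schedule,
                                  REFERENCE_REGION)

    n_frames = schedule.n_frames
    image = np.empty(grid_shape + (n_frames,), dtype=float)
    for lab, tac in region_tac.items():
        image[labels == lab, :] = tac.activity
    if noise_scale > 0:
        t_mid = schedule.mid_min
        dt = schedule.durations_min
        sd = noise_scale * np.sqrt(
            np.maximum(image, 0.0) * np.exp(F18_DECAY_CONST_PER_MIN * t_mid) / dt
        )
        image = image + rng.normal(0.0, 1.0, image.shape) * sd
    return image, labels, label_names
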