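"""Reference-tissue Logan analysis: transform identities, fit recovery
against the simulator's analytic Vt-ratio truth, and voxelwise maps."""

import numpy as np
import pytest
from scipy import integrate

import fespet
from fespet.kinetics import TimeActivityCurve
from fespet.logan import (
    LoganPoints,
    LoganReferenceModel,
    cumulative_integral,
    fit_logan,
    logan_transform,
    parametric_bpnd,
    roi_dvr_table,
    select_t_star,
)
from fespet.simulate import REFERENCE_KINETICS, kinetics_for_dvr, simulate_voxel_image


# ---------------------------------------------------------------------------
# cumulative integration
# ---------------------------------------------------------------------------

def test_cumulative_integral_of_constant_and_zero(schedule):
    const = TimeActivityCurve(schedule, np.ones(30))
    assert cumulative_integral(const)[-1] == pytest.approx(90.0)
    zero = TimeActivityCurve(schedule, np.zeros(30))
    np.testing.assert_array_equal(cumulative_integral(zero), 0.0)


def test_cumulative_integral_tracks_quadrature_of_smooth_curve(schedule, aif):
    kin = kinetics_for_dvr(1.8)
    curve = fespet.tissue_curve(aif, kin)
    tac = fespet.frame_average(curve, schedule)
    ours = cumulative_integral(tac)
    for i in np.nonzero(schedule.ends_min >= 10)[0][::6]:
        oracle, _ = integrate.quad(
            lambda t: float(curve(np.array([t]))[0]), 0, schedule.ends_min[i], limit=300
        )
        assert ours[i] == pytest.approx(oracle, rel=5e-3)


# ---------------------------------------------------------------------------
# transform identities
# ---------------------------------------------------------------------------

def test_identical_curves_give_y_equals_x(reference_tac):
    pts = logan_transform(reference_tac, reference_tac)
    np.testing.assert_allclose(pts.y, pts.x, rtol=1e-12)


def test_doubled_target_gives_exact_slope_two(reference_tac):
    target = reference_tac.with_activity(2.0 * reference_tac.activity)
    pts = logan_transform(target, reference_tac)
    fit = fit_logan(pts, t_star=20.0)
    assert fit.dvr == pytest.approx(2.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_mismatched_schedules_rejected(reference_tac):
    short = fespet.FrameSchedule(np.array([0.0, 60.0]), np.array([60.0, 120.0]))
    other = TimeActivityCurve(short, np.ones(2))
    with pytest.raises(ValueError, match="schedule"):
        logan_transform(other, reference_tac)


def test_nonpositive_target_frames_dropped_with_warning(reference_tac):
    act = reference_tac.activity.copy()
    act[10] = -0.5
    target = reference_tac.with_activity(act)
    with pytest.warns(UserWarning, match="non-positive"):
        pts = logan_transform(target, reference_tac)
    # the first frame (pre-arrival, zero activity) is also dropped
    assert pts.x.size <= 28


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_collinear_points_recover_exact_slope():
    t = np.linspace(10, 80, 12)
    x = np.linspace(5, 50, 12)
    pts = LoganPoints(t_mid=t, x=x, y=2.0 * x - 3.0)
    fit = fit_logan(pts, t_star=15.0)
    assert fit.dvr == pytest.approx(2.0, abs=1e-12)
    assert fit.bpnd == pytest.approx(1.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_requires_enough_late_points_and_x_spread():
    pts = LoganPoints(t_mid=np.array([10.0, 20, 30, 40]), x=np.arange(4.0),
                      y=np.arange(4.0))
    with pytest.raises(ValueError, match=">= 3 points"):
        fit_logan(pts, t_star=25.0)
    flat = LoganPoints(t_mid=np.array([40.0, 50, 60]), x=np.ones(3), y=np.arange(3.0))
    with pytest.raises(ValueError, match="variance"):
        fit_logan(flat, t_star=30.0)


@pytest.mark.parametrize("true_dvr", [1.2, 1.5, 2.0, 2.5])
def test_noise_free_dvr_recovery_within_five_percent(
    true_dvr, make_target_tac, reference_tac
):
    model = LoganReferenceModel(t_star=30.0).fit(make_target_tac(true_dvr), reference_tac)
    assert abs(model.dvr_ - true_dvr) / true_dvr < 0.05


def test_identity_target_gives_dvr_exactly_one(reference_tac):
    model = LoganReferenceModel().fit(reference_tac, reference_tac)
    assert model.dvr_ == pytest.approx(1.0, abs=1e-6)
    assert model.bpnd_ == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("scale", [1e-3, 0.5, 7.0, 1e4])
def test_dvr_invariant_to_global_rescaling(scale, make_target_tac, reference_tac):
    target = make_target_tac(1.9)
    base = LoganReferenceModel().fit(target, reference_tac).dvr_
    scaled = LoganReferenceModel().fit(
        target.with_activity(scale * target.activity),
        reference_tac.with_activity(scale * reference_tac.activity),
    ).dvr_
    assert scaled == pytest.approx(base, rel=1e-12)


def test_k2prime_term_reduces_bias_for_slow_reference_efflux(schedule, aif):
    """With slow reference washout the reference-TAC-only transform is
    biased; supplying the true k2' must shrink the absolute bias."""
    from fespet.kinetics import CompartmentParams

    slow_ref_kin = CompartmentParams(K1=0.2, k2=0.05, vb=0.05)
    true_dvr = 2.0
    kin = CompartmentParams(K1=0.2, k2=0.05, k3=0.08 * (true_dvr - 1), k4=0.08, vb=0.05)
    ref = fespet.frame_average(fespet.tissue_curve(aif, slow_ref_kin), schedule)
    tac = fespet.frame_average(fespet.tissue_curve(aif, kin), schedule)
    plain = LoganReferenceModel(t_star=30.0).fit(tac, ref).dvr_
    corrected = LoganReferenceModel(t_star=30.0, k2prime=slow_ref_kin.k2).fit(tac, ref).dvr_
    assert abs(corrected - true_dvr) < abs(plain - true_dvr)


# ---------------------------------------------------------------------------
# t* selection
# ---------------------------------------------------------------------------

def test_collinear_points_select_earliest_midpoint():
    t = np.linspace(10, 80, 10)
    x = np.linspace(5, 60, 10)
    pts = LoganPoints(t_mid=t, x=x, y=1.5 * x + 2.0)
    assert select_t_star(pts) == pytest.approx(t[0])


def test_curved_then_linear_points_select_start_of_linear_segment():
    t = np.linspace(5, 85, 17)
    x = np.linspace(2, 60, 17)
    y = 2.0 * x + 1.0
    curved = t < 40
    y[curved] -= 30.0 * (40 - t[curved]) / 40  # strong early curvature
    pts = LoganPoints(t_mid=t, x=x, y=y)
    chosen = select_t_star(pts, max_rel_deviation=0.02)
    # brute-force oracle: smallest start index whose tail is within tolerance
    def tail_ok(i):
        slope, inter = np.polyfit(x[i:], y[i:], 1)
        pred = inter + slope * x[i:]
        return np.max(np.abs(y[i:] - pred) / np.abs(pred)) <= 0.02
    oracle = t[min(i for i in range(t.size - 2) if tail_ok(i))]
    assert chosen == pytest.approx(oracle)
    assert chosen >= 40 - 5.0  # inside the linear segment


def test_always_curved_points_fall_back_to_30_min():
    t = np.linspace(5, 85, 12)
    x = np.linspace(2, 60, 12)
    pts = LoganPoints(t_mid=t, x=x, y=x**2)
    with pytest.warns(UserWarning, match="falling back"):
        assert select_t_star(pts, max_rel_deviation=0.001) == 30.0


# ---------------------------------------------------------------------------
# parametric maps and ROI tables
# ---------------------------------------------------------------------------

def test_parametric_map_matches_roi_fit_and_masks_antibinding(reference_tac):
    kin_map = {"hot": kinetics_for_dvr(2.0),
               "anti": fespet.CompartmentParams(K1=0.1, k2=0.2, vb=0.05)}  # Vt < Vt'
    img, labels, names = simulate_voxel_image((6, 3, 3), kin_map, noise_scale=0.0)
    bmap = parametric_bpnd(img, reference_tac)
    hot = [k for k, v in names.items() if v == "hot"][0]
    anti = [k for k, v in names.items() if v == "anti"][0]
    roi_fit = LoganReferenceModel().fit(
        TimeActivityCurve(reference_tac.schedule, img[labels == hot][0]), reference_tac
    )
    hot_vals = bmap.bpnd[labels == hot]
    assert np.all(np.isfinite(hot_vals))
    np.testing.assert_allclose(hot_vals, roi_fit.bpnd_, atol=1e-6)
    # the anti-binding block has BPnd <= 0 everywhere: all voxels masked
    assert not bmap.mask[labels == anti].any()
    assert np.isnan(bmap.bpnd[labels == anti]).all()
    assert bmap.roi_mean_dvr(labels, hot) == pytest.approx(1.0 + roi_fit.bpnd_, abs=1e-6)


def test_parametric_map_rejects_frame_mismatch(reference_tac):
    with pytest.raises(ValueError, match="frames"):
        parametric_bpnd(np.zeros((2, 2, 2, 10)), reference_tac)


def test_roi_dvr_table_identity_and_determinism(small_cohort):
    table = roi_dvr_table(small_cohort.tacs)
    assert len(table) == 15 * 3
    np.testing.assert_allclose(table["dvr"], 1.0 + table["bpnd"], rtol=0, atol=0)
    again = roi_dvr_table(small_cohort.tacs)
    assert table.equals(again)


def test_roi_dvr_table_recovers_truth_noise_free():
    design = fespet.default_cohort_design(seed=5, noise_scale=0.0)
    cohort = fespet.simulate_cohort(design)
    table = roi_dvr_table(cohort.tacs).merge(cohort.truth, on=["subject_id", "region"])
    rel = np.abs(table["dvr"] - table["true_dvr"]) / table["true_dvr"]
    assert rel.max() < 0.05


def test_missing_reference_tac_is_an_error(small_cohort):
    tacs = {"S000": {k: v for k, v in small_cohort.tacs["S000"].items()
                     if k != "cerebellum"}}
    with pytest.raises(ValueError, match="reference"):
        roi_dvr_table(tacs)
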