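import warnings

import numpy as np
import pytest

import fespet
from fespet.simulate import REFERENCE_KINETICS, kinetics_for_dvr

warnings.filterwarnings("ignore", message=".*non-positive target activity.*")


@pytest.fixture(scope="session")
def schedule():
    return fespet.default_schedule()


@pytest.fixture(scope="session")
def aif():
    return fespet.InputFunctionParams()


@pytest.fixture(scope="session")
def reference_tac(schedule, aif):
    return fespet.frame_average(
        fespet.tissue_curve(aif, REFERENCE_KINETICS), schedule, "cerebellum"
    )


@pytest.fixture(scope="session")
def make_target_tac(schedule, aif):
    """Noise-free framed TAC for a binding region of given true DVR."""

    def _make(dvr: float, region: str = "target") -> fespet.TimeActivityCurve:
        kin = kinetics_for_dvr(dvr)
        return fespet.frame_average(fespet.tissue_curve(aif, kin), schedule, region)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort (3 regions, 5/5/5 subjects) for unit tests."""
    regions = {
        "pituitary": fespet.simulate.RegionEffect(1.50, 1.77, 2.04, 0.45),
        "hippocampus": fespet.simulate.RegionEffect(1.30, 1.38, 1.46, 0.18),
        "caudate": fespet.simulate.RegionEffect(1.15, 1.17, 1.20, 0.15),
    }
    design = fespet.CohortDesign(
        n_per_group={"PRE": 5, "PERI": 5, "POST": 5}, regions=regions,
        noise_scale=0.1, seed=42,
    )
    return fespet.simulate_cohort(design)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the study-conditions design."""
    return fespet.simulate_cohort(fespet.default_cohort_design(seed=7))
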