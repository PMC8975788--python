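import numpy as np
import pytest

import ipdmed as im
from ipdmed import Arm
from ipdmed.simulate import SimulationDesign, StudyDesign


@pytest.fixture(scope="session")
def preset_design():
    return im.preset_integrate_like()


@pytest.fixture(scope="session")
def complete_data(preset_design):
    """One complete (no missingness) dataset from the packaged preset, with truth."""
    return im.generate_multistudy(preset_design, seed=101)


@pytest.fixture(scope="session")
def masked_data(preset_design, complete_data):
    """The same dataset after MAR masking."""
    ds, truth = complete_data
    return im.apply_mar_missingness(ds, preset_design, rng=101), truth


def make_small_design(**overrides) -> SimulationDesign:
    """Compact 3-study design for fast tests.

    Study A mirrors an MI+PF-vs-control trial of all first-year students;
    study C an all-female GMI-vs-control trial; study B evaluates PF and GMI and
    carries baseline-mediator missingness.
    """
    studies = [
        StudyDesign("A", {Arm.CONTROL: 40, Arm.MIPF: 40}, female_n=45, firstyr_n=80,
                    nonwhite_n=20, bl_mediator_mean=0.4, bl_mediator_sd=0.9,
                    bl_outcome_mean=0.1, bl_outcome_sd=0.9,
                    missing_n={}),
        StudyDesign("B", {Arm.CONTROL: 40, Arm.PF: 40, Arm.GMI: 40}, female_n=70,
                    firstyr_n=60, nonwhite_n=30, bl_mediator_mean=0.5,
                    bl_mediator_sd=0.8, bl_outcome_mean=0.2, bl_outcome_sd=1.0,
                    missing_n={"bl_mediator": 24, "post_mediator": 4}),
        StudyDesign("C", {Arm.CONTROL: 40, Arm.GMI: 40}, female_n=80, firstyr_n=50,
                    nonwhite_n=25, bl_mediator_mean=0.6, bl_mediator_sd=1.0,
                    bl_outcome_mean=0.0, bl_outcome_sd=0.8,
                    missing_n={"bl_mediator": 12}),
    ]
    kw = dict(
        studies=studies,
        eqA_coef={"intercept": 0.1, "TX_MIPF": 0.05, "TX_PF": 0.1, "TX_GMI": 0.05,
                  "BL_ALCPROB": -0.05, "BL_PBS": 0.6, "MALE": -0.1, "FIRSTYR": -0.05,
                  "NONWHITE": 0.05},
        eqB_coef={"intercept": 0.1, "TX_MIPF": -0.02, "TX_PF": 0.01, "TX_GMI": -0.03,
                  "BL_ALCPROB": 0.6, "BL_PBS": 0.02, "POST_PBS": -0.25, "MALE": 0.05,
                  "FIRSTYR": 0.02, "NONWHITE": -0.02},
        resid_sd_A=0.7,
        resid_sd_B=0.7,
        seed=13,
    )
    kw.update(overrides)
    return SimulationDesign(**kw)


@pytest.fixture(scope="session")
def small_design():
    return make_small_design()


@pytest.fixture(scope="session")
def small_data(small_design):
    return im.generate_multistudy(small_design, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
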