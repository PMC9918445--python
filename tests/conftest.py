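import numpy as np
import pytest

from crctwin import (
    ModelSpec,
    MortalitySchedule,
    RateParameters,
    ScreeningDesign,
)
from crctwin import datasets
from crctwin.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def spec3():
    return ModelSpec("progressive_3state")


@pytest.fixture(scope="session")
def spec_od():
    return ModelSpec("overdiag_embedded")


@pytest.fixture(scope="session")
def spec_aden():
    return ModelSpec("adenoma_overdiag")


@pytest.fixture(scope="session")
def taiwan_rates():
    return RateParameters(lambda1=0.00141, lambda2=0.3860, sens_crc=0.8025)


@pytest.fixture(scope="session")
def mort0():
    return MortalitySchedule.constant(0.0)


@pytest.fixture(scope="session")
def mort01():
    return MortalitySchedule.constant(0.01)


@pytest.fixture(scope="session")
def small_design():
    return ScreeningDesign(
        screen_times=(0.0, 2.0, 4.0),
        followup_T=11.0,
        cohort_size=200_000,
        participation=0.7,
        confirmation_rate=0.9,
    )


@pytest.fixture(scope="session")
def sim_rates():
    return RateParameters(
        lambda1=0.0015, lambda2=0.40, sens_crc=0.80, nonprog_fraction=0.05
    )


@pytest.fixture(scope="session")
def simulated_cohort(spec_od, sim_rates, mort01, small_design):
    """One shared 200k-subject simulated screening cohort."""
    cfg = SimulationConfig(
        spec=spec_od, rates=sim_rates, mort=mort01, design=small_design, seed=42
    )
    return simulate_cohort(cfg, return_individuals=True)
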