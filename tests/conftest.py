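import numpy as np
import pytest
from hypothesis import settings

from cgmcea import (
    build_parameters,
    calibrate_baseline,
    default_parameter_table,
    run_psa,
)
from cgmcea.mortality import MortalitySchedule
from cgmcea.states import State

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specs():
    return default_parameter_table()


@pytest.fixture(scope="session")
def params():
    return build_parameters()


@pytest.fixture(scope="session")
def schedule():
    """Synthetic mortality calibrated so the SMBG cohort's life expectancy is 73."""
    return calibrate_baseline(73.0)


@pytest.fixture(scope="session")
def flat_schedule():
    """Constant 1% baseline mortality, no state-specific excess."""
    ages = np.arange(40, 116)
    mult = {s: 1.0 for s in State if s is not State.DEATH}
    return MortalitySchedule(ages, np.full(ages.size, 0.01), mult)


@pytest.fixture(scope="session")
def zero_mortality_schedule():
    ages = np.arange(40, 116)
    mult = {s: 1.0 for s in State if s is not State.DEATH}
    return MortalitySchedule(ages, np.zeros(ages.size), mult)


@pytest.fixture(scope="session")
def psa_10k(specs, schedule):
    """One shared 10,000-draw PSA used by the Monte Carlo summary tests."""
    return run_psa(specs, schedule, n=10_000, seed=20_210_914)
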