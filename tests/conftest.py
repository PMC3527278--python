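import numpy as np
import pytest

import asthmasim as a


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def default_cfg():
    return a.ScenarioConfig(n_children=10, years=2, seed=0)


@pytest.fixture
def household():
    """A fully featured home: gas stove, supplemental heat, heavy smoker."""
    return a.Household(
        gas_stove=True, supplemental_heat_user=True,
        below_average_housekeeping=True, smoker="heavy",
        apartment_level="lower", leakiness="II", fans_operational=False,
        holes_in_walls=True, allergen_category=1,
    )


@pytest.fixture
def clean_household():
    """A home with no indoor combustion or smoking sources and fans on."""
    return a.Household(
        gas_stove=False, supplemental_heat_user=False,
        below_average_housekeeping=False, smoker="none",
        apartment_level="lower", leakiness="III", fans_operational=True,
        holes_in_walls=False, allergen_category=3,
    )
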