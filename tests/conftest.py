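import numpy as np
import pytest

from smokehia.synthetic_data import ScenarioSpec, generate_scenario


@pytest.fixture(scope="session")
def small_spec():
    """A 10×10×5 scenario: big enough to exercise every stage, seconds-fast."""
    return ScenarioSpec(grid_nx=10, grid_ny=10, n_days=5, n_counties=3,
                        tract_size=3, seed=7)


@pytest.fixture(scope="session")
def small_scenario(small_spec):
    return generate_scenario(small_spec)


@pytest.fixture(scope="session")
def default_scenario():
    """The reference 40×40×13 scenario with default plumes and noise."""
    return generate_scenario(ScenarioSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
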