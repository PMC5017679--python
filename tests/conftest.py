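import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")

from strem.landscape import StudyDomain, uniform_raster
from strem.movement import (MovementConfig, ScenarioSpec, init_population,
                            simulate_season)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def big_domain():
    """Large homogeneous domain where boundary effects are negligible."""
    return StudyDomain.rectangle(1500.0, 1500.0)


@pytest.fixture(scope="session")
def big_raster(big_domain):
    return uniform_raster(big_domain.bounds, cell_size=25.0)


@pytest.fixture(scope="session")
def scenario_a_traj(big_domain, big_raster):
    """One season of plain correlated-random-walk movement, 200 agents."""
    rng = np.random.default_rng(777)
    spec = ScenarioSpec.from_code("A", initial_n=200)
    cfg = MovementConfig()
    pop = init_population(spec, big_domain, big_raster, cfg, rng)
    return simulate_season(pop, spec, big_domain, big_raster, cfg, rng,
                           days=50)
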