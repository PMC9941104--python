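import numpy as np
import pytest
from hypothesis import settings

import valveshape as vs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """8 species x 3 specimens x 2 valves, all effects at default strength."""
    params = vs.SimulationParams(n_species=8, specimens_per_species=3)
    return vs.simulate_dataset(params=params, seed=11)


@pytest.fixture(scope="session")
def small_aligned(small_sim):
    ds = small_sim.dataset()
    configs = [vs.reflect_side(c, "left") for c in ds.configurations]
    aligned = vs.tangent_project(vs.gpa(configs))
    return ds, aligned
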