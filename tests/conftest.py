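import numpy as np
import pytest

from yeastvigor.simulate import SimulationParams, generate_dataset


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A reduced study design: 7 strains, 3 environments, 3 replicates."""
    return SimulationParams(
        n_dom=4, n_wild=3, n_env=3, n_rep_hom=3, n_rep_het=3
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """One fully synthetic small study (OD plates and agar assays included)."""
    return generate_dataset(small_params, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
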