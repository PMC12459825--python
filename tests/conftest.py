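import numpy as np
import pytest

import srmkit
from srmkit.inference import fit
from srmkit.models import build_spec


@pytest.fixture(scope="session")
def scm1_network():
    """A small simulated random-features network reused across tests."""
    return srmkit.simulate(srmkit.ScmConfig(scm_id=1, seed=11, n_individuals=12))


@pytest.fixture(scope="session")
def scm1_posterior(scm1_network):
    """A short variant-1 fit on the small network (shared to save sampling time)."""
    return fit(
        build_spec(1), scm1_network.dataset,
        chains=2, iterations=400, warmup=300, seed=3,
    )


@pytest.fixture(scope="session")
def scm4_network():
    return srmkit.simulate(srmkit.ScmConfig(scm_id=4, seed=4))


@pytest.fixture(scope="session")
def scm3_network():
    return srmkit.simulate(srmkit.ScmConfig(scm_id=3, seed=9))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
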