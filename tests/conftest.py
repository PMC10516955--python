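import numpy as np
import pytest
from hypothesis import settings

import snapgmm as sg

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def linear6():
    return sg.fixture_network("linear6")


@pytest.fixture(scope="session")
def msn2():
    return sg.fixture_network("msn2")


@pytest.fixture(scope="session")
def vav1():
    return sg.fixture_network("vav1")


@pytest.fixture(scope="session")
def cd8_chain():
    return sg.fixture_network("cd8_chain")


@pytest.fixture(scope="session")
def linear6_cells():
    """A small lognormal cell population for the linear6 model."""
    return sg.sample_lognormal_cells(np.ones(6), 0.4 * np.ones(6), 200, seed=42)


def make_self_consistent(net, x0, times, **evolve_kwargs):
    """Dataset whose observations are the initial cells themselves evolved
    under the file parameters — the GMM cost at truth is then ~0."""
    pops = sg.evolve_cells(net, net.theta_file(), x0, times, **evolve_kwargs)
    return sg.SnapshotDataset(
        x0=x0, observations=[(p.time, p.states) for p in pops],
        species_order=list(net.species),
    )


@pytest.fixture(scope="session")
def linear6_selfconsistent(linear6, linear6_cells):
    return make_self_consistent(linear6, linear6_cells, [1.5])
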