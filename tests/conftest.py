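import numpy as np
import pytest

from alffnet import genetics, simulate


@pytest.fixture(scope="session")
def panel():
    return genetics.load_panel()


@pytest.fixture(scope="session")
def sim_panel():
    return simulate.default_panel()


@pytest.fixture(scope="session")
def small_genotypes(sim_panel):
    return simulate.generate_genotypes(73, sim_panel, seed=11)


@pytest.fixture(scope="session")
def small_phenotypes():
    return simulate.generate_phenotypes(43, 30, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
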