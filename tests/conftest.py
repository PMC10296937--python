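import numpy as np
import pytest

import selintro as si


@pytest.fixture(scope="session")
def gmap_default():
    return si.GeneticMap.default()


@pytest.fixture(scope="session")
def bc2f4_large(gmap_default):
    """Unselected BC2F4, 5000 lines on the default 210-marker map."""
    return si.simulate_bc2f4_population(n_lines=5000, gmap=gmap_default, seed=123)


@pytest.fixture(scope="session")
def table1():
    """Published progeny-test means of the nine promising lines and the check."""
    return si.load_promising_lines()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def two_marker_map():
    """Two markers 50 cM apart on one chromosome."""
    return si.GeneticMap(("mA", "mB"), np.array([1, 1]), np.array([0.0, 50.0]))
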