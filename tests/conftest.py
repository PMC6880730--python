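import numpy as np
import pytest

from lpnmf import generate_fixture
from lpnmf.io import OntologyGraph


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic dataset shared across tests."""
    return generate_fixture(
        n_lncrna=20, n_protein=6, d_true=3, density=0.15, noise_rate=0.0,
        n_tissues=5, n_terms=15, seed=42,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The default study-condition fixture (40 x 12, planted rank 4)."""
    return generate_fixture(seed=7)


@pytest.fixture
def toy_dag():
    """Two-term chain A --is_a--> B used for hand-computed semantic
    similarity values."""
    return OntologyGraph.from_edges([("A", "B", "is_a")])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
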