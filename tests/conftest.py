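import numpy as np
import pytest

from paleodup.simulate import EvolutionParams, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared across tests (300 ref genes)."""
    return simulate(EvolutionParams(seed=11, n_ref_genes=300,
                                    n_tandem_arrays=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
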