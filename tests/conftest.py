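import numpy as np
import pytest

import mhcequity.synthetic_data as sd


@pytest.fixture(scope="session")
def small_universe():
    """50 alleles in 5 clusters with moderate within-cluster divergence."""
    return sd.generate_allele_universe(n_alleles=50, n_clusters=5, mutation_rate=0.05, seed=1)


@pytest.fixture(scope="session")
def oracle(small_universe):
    return sd.make_binding_oracle(small_universe, noise_sd=0.5, seed=2)


@pytest.fixture(scope="session")
def proteome():
    return sd.sample_proteome(n_proteins=20, length=300, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
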