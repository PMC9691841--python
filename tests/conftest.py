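import numpy as np
import pytest

from mrnet.synthetic import generate_cohort, generate_network, true_regulon_set


@pytest.fixture(scope="session")
def small_truth():
    """A compact planted network: 10 TFs, 300 genes, regulons of 15-25."""
    return generate_network(10, 300, (15, 25), 0.3, 0.2, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return generate_cohort(small_truth, 40, 20, effect_size=2.0, noise_sd=1.0, seed=8)


@pytest.fixture(scope="session")
def small_regulons(small_truth):
    return true_regulon_set(small_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
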