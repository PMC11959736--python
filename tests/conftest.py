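import numpy as np
import pytest

from foreststab import SimSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_regression():
    """n=60, p=120 few-strong regression data set with its truth record."""
    return simulate_dataset(
        SimSpec(n_individuals=60, n_snps=120, heritability=0.6, seed=3)
    )


@pytest.fixture(scope="session")
def small_classification():
    return simulate_dataset(
        SimSpec(n_individuals=60, n_snps=120, heritability=0.6,
                task="classification", seed=4)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
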