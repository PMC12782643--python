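import numpy as np
import pytest

import mupsim as m


@pytest.fixture(scope="session")
def pop_mid():
    """Mid-sized calibrated population shared across read-only tests."""
    return m.generate_population(50_000, seed=1)


@pytest.fixture(scope="session")
def inputs_small():
    """Small full input bundle for engine tests."""
    return m.generate_inputs(n=5_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_distribution(rng, max_points=10, subgroup=0, beverage="off-trade:beer"):
    """Random valid price distribution for property tests."""
    k = int(rng.integers(1, max_points + 1))
    prices = np.sort(rng.uniform(0.2, 3.0, size=k))
    prices += np.arange(k) * 1e-6  # strictly increasing
    shares = rng.dirichlet(np.ones(k))
    shares = np.maximum(shares, 1e-9)
    shares /= shares.sum()
    return m.PriceDistribution(
        prices=prices, shares=shares, subgroup=subgroup, beverage=beverage)
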