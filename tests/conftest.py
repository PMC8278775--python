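import numpy as np
import pytest

from incval.distributions import (
    BinormalSpec,
    make_binormal_pair,
)

# the three hypothetical binormal risk scores used across the suite:
# shared standard-normal non-events; event distributions N(1.8, sd 2),
# N(1.5, sd 1.5) and N(3, sd 1.5)
R1 = BinormalSpec(1.8, 2.0)
R2 = BinormalSpec(1.5, 1.5)
R3 = BinormalSpec(3.0, 1.5)


@pytest.fixture(scope="session")
def r1_pair():
    return make_binormal_pair(R1)


@pytest.fixture(scope="session")
def r2_pair():
    return make_binormal_pair(R2)


@pytest.fixture(scope="session")
def r3_pair():
    return make_binormal_pair(R3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def random_binormal_specs(rng, n):
    """Random informative binormal specs for property tests."""
    specs = []
    for _ in range(n):
        mu1 = rng.uniform(0.2, 3.0)
        sd1 = rng.uniform(0.5, 2.5)
        sd0 = rng.uniform(0.5, 2.0)
        specs.append(BinormalSpec(mu1, sd1, 0.0, sd0))
    return specs
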