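import warnings

import numpy as np
import pytest

from rbpscore import build_world_context, worked_example
from rbpscore.simulate import FixtureSpec, simulate_world


@pytest.fixture(scope="session")
def worked():
    return worked_example()


@pytest.fixture(scope="session")
def worked_ctx(worked):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_world_context(worked, worked.config)


@pytest.fixture(scope="session")
def small_world():
    """One deterministic synthetic world shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_world(FixtureSpec(seed=20240917))


@pytest.fixture(scope="session")
def small_ctx(small_world):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_world_context(small_world)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
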