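import numpy as np
import pytest

import equipanel as eq


@pytest.fixture(scope="session")
def western_panel():
    """Packaged western-China density panel (no attributes)."""
    return eq.load_western_china()


@pytest.fixture(scope="session")
def western_weighted(western_panel):
    """Western densities joined with synthetic provincial-scale attributes."""
    return western_panel.with_attributes(eq.western_synthetic_attributes(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_allocation(rng, n=None):
    n = int(n if n is not None else rng.integers(2, 31))
    return eq.AllocationVector(
        region_ids=tuple(f"r{i:02d}" for i in range(n)),
        weights=rng.random(n) + 0.01,
        amounts=rng.random(n) + 1e-6,
    )
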