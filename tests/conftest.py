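import numpy as np
import pytest

from fabof import DGPConfig, OrdinalDataset, fit_fabof, simulate_ordinal


@pytest.fixture(scope="session")
def small_pool():
    """A small proportional-odds pool shared across tests (k=5, n=600)."""
    cfg = DGPConfig(dgp=1, n=300, k=5, pattern="equal", pool_size=600,
                    pilot_n=20_000, seed=20240)
    return simulate_ordinal(cfg)


@pytest.fixture(scope="session")
def small_model(small_pool):
    """A small fitted fabOF model (100 trees) shared across tests."""
    return fit_fabof(small_pool, trees=100, seed=7)


@pytest.fixture()
def tiny_dataset():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 4))
    y = np.clip(np.round(2.5 + X[:, 0]).astype(int), 1, 4)
    return OrdinalDataset(X, y, 4)
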