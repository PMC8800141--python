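import numpy as np
import pandas as pd
import pytest

from intersectprev import ScenarioConfig, simulate_dataset


@pytest.fixture(scope="session")
def rare_categorical_small():
    """One rare-tier categorical dataset at N=2000."""
    return simulate_dataset(ScenarioConfig("categorical", "rare", 2000,
                                           master_seed=11), 0)


@pytest.fixture(scope="session")
def common_categorical_mid():
    """One common-tier categorical dataset at N=20000."""
    return simulate_dataset(ScenarioConfig("categorical", "common", 20000,
                                           master_seed=12), 0)


@pytest.fixture(scope="session")
def rare_mixed_mid():
    """One rare-tier mixed-inputs dataset at N=10000."""
    return simulate_dataset(ScenarioConfig("mixed", "rare", 10000,
                                           master_seed=13), 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def null_frame():
    """Covariates shaped like the categorical model, outcome independent."""
    r = np.random.default_rng(5)
    n = 800
    return pd.DataFrame({
        "x1": r.integers(0, 4, n), "x2": r.integers(0, 2, n),
        "x3": r.integers(0, 2, n), "x4": r.integers(0, 2, n),
        "x5": r.integers(0, 2, n), "x6": r.integers(0, 3, n),
        "y": r.integers(0, 2, n),
    })
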