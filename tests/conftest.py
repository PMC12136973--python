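import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import dielomics as dl

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_design() -> pd.DataFrame:
    return dl.build_design()


@pytest.fixture(scope="session")
def small_dataset():
    """Small default-condition synthetic experiment shared across tests."""
    cfg = dl.SimConfig(seed=11, n_genes=300)
    return dl.simulate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
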