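import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ctap
from ctap.comparison_pairs import CohortMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def registry():
    return ctap.bundled_fg_registry()


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic cohort (seeded) with its ground truth."""
    cohort, truth = ctap.simulated_cohort(ctap.SimConfig(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def default_cohort(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def training_samples(default_cohort, registry):
    return ctap.build_training_set(default_cohort, registry)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free cohort without platform effects or abundance coding."""
    config = ctap.SimConfig(
        seed=3,
        noise_sd=0.0,
        platform_log2_gain_range=(0.0, 0.0),
        platform_offset_range=(0.0, 0.0),
        abundance_coded_fraction=0.0,
    )
    cohort, truth = ctap.simulated_cohort(config)
    return cohort, truth


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(7)
    return CohortMatrix(pd.DataFrame(
        rng.lognormal(4.0, 1.0, size=(50, 4)),
        index=[f"G{i:03d}" for i in range(50)],
        columns=["1:control", "1:test", "2:control", "2:test"],
    ))
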