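import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chromage.io import CountMatrix
from chromage.synthetic import StudyConfig, generate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _silence_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed 11)."""
    return generate_study(StudyConfig(seed=11))


@pytest.fixture(scope="session")
def benchmark_study():
    """Balanced five-profile study for clustering tests (seed 11)."""
    return generate_study(StudyConfig.five_profile_benchmark(seed=11))


@pytest.fixture()
def small_counts():
    """Tiny deterministic raw count matrix, 4 regions x 4 samples."""
    rng = np.random.default_rng(5)
    data = pd.DataFrame(
        rng.integers(10, 200, size=(4, 4)),
        index=[f"r{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(4)],
    )
    return CountMatrix(data, mark="H3K27ac")
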