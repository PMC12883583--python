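import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from riclpm import build_riclpm
from riclpm.reference import default_schedule
from riclpm.synthetic import MissingSpec, alspac_like_truth, simulate_panel


@pytest.fixture(scope="session")
def truth():
    return alspac_like_truth()


@pytest.fixture(scope="session")
def index6():
    return build_riclpm(6)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def small_raw_panel(truth):
    """A small raw-scale panel with MAR missingness (seed-stable)."""
    return simulate_panel(truth, n=300, missing=MissingSpec.alspac_like(), seed=11)


@pytest.fixture(scope="session")
def model_scale_panel(truth):
    """Complete normalized-scale panel: the exact model world."""
    return simulate_panel(truth.model_scale(), n=800, seed=5)
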