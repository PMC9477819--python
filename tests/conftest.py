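import pytest

from pavpan.alignment import build_index
from pavpan.config import Thresholds
from pavpan.synthetic_data import default_params, simulate_study


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_params():
    """A small two-cohort study used across the suite (8 samples)."""
    return default_params(seed=1, n_per_cohort=4)


@pytest.fixture(scope="session")
def small_study(small_params):
    return simulate_study(small_params)


@pytest.fixture(scope="session")
def ref_index(small_study):
    return build_index(small_study.reference.chromosomes)
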