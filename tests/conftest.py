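import numpy as np
import pytest

from enclospace.geometry import (
    build_unfolded_surface,
    complex_enclosure,
    default_zone_partition,
    standard_enclosure,
)
from enclospace.synth import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def standard_spec():
    return standard_enclosure()


@pytest.fixture(scope="session")
def complex_spec():
    return complex_enclosure()


@pytest.fixture(scope="session")
def standard_surface(standard_spec):
    return build_unfolded_surface(standard_spec)


@pytest.fixture(scope="session")
def complex_surface(complex_spec):
    return build_unfolded_surface(complex_spec)


@pytest.fixture(scope="session")
def complex_zones(complex_surface):
    return default_zone_partition(complex_surface)


@pytest.fixture(scope="session")
def small_config():
    """A fast synthetic study: fewer subjects and sessions, same structure."""
    return SyntheticConfig(seed=11, n_subjects=6, n_males=2,
                           sessions_per_condition=12)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
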