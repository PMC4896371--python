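import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pytradis.simulate import SimulationConfig, simulate, write_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lib():
    """Default-condition simulated library shared by read-only tests."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def clean_lib():
    """Error-free, contaminant-free library: every read is tagged and
    derives verbatim from the genome."""
    return simulate(SimulationConfig(seed=12, frac_untagged=0.0, base_error_rate=0.0))


@pytest.fixture(scope="session")
def fixture_dir(small_lib, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(small_lib, str(d), force=True)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
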