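import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lagshift import synthetic
from lagshift.config import SimulationConfig

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(n_studies=3, sites_per_study=4,
                            series_start="2000-01", series_end="2012-12",
                            break_time_range=("2003-01", "2010-12"),
                            sample_start_range=("2009-01", "2012-12"),
                            seed=42)


@pytest.fixture(scope="session")
def tiny_landscape(tiny_config):
    return synthetic.simulate_all(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250923)
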