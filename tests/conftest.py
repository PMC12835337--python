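import numpy as np
import pytest

from runstride.config import PipelineConfig
from runstride.pipeline import analyze
from runstride.simulate import GaitProfile, simulate_run


@pytest.fixture(scope="session")
def default_profile():
    return GaitProfile(seed=11)


@pytest.fixture(scope="session")
def clean_profile():
    """Noise-free default run (exact construction checks)."""
    return GaitProfile(seed=11, sigma_acc=0.0, sigma_gyr=0.0, gyro_bias=0.0)


@pytest.fixture(scope="session")
def sim_default(default_profile):
    return simulate_run(default_profile)


@pytest.fixture(scope="session")
def sim_clean(clean_profile):
    return simulate_run(clean_profile)


@pytest.fixture(scope="session")
def results_default(sim_default):
    rec, _ = sim_default
    return analyze(rec, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
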