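import numpy as np
import pytest

from freshcube import scene_sim as ss
from freshcube.core import SampleRecord


@pytest.fixture(scope="session")
def default_params():
    return ss.ScenarioParams()


@pytest.fixture(scope="session")
def small_params():
    """Small, quiet scene for fast pipeline tests."""
    return ss.ScenarioParams(height=32, width=32, noise_sd=0.001,
                             illumination_tilt_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_params():
    return ss.ScenarioParams(height=32, width=32, noise_sd=0.0,
                             illumination_tilt_sd=0.0,
                             illumination_min=1.0)


@pytest.fixture(scope="session")
def library(default_params):
    return ss.make_endmember_library(default_params.grid(), default_params)


@pytest.fixture(scope="session")
def working_library(default_params):
    return ss.working_endmembers(default_params)


@pytest.fixture(scope="session")
def sample_record():
    return SampleRecord(sample_id="T25_D05_R1", temperature=25.0, day=5,
                        replicate=1, glucosinolate=80.0)


@pytest.fixture(scope="session")
def rendered_sample(small_params, sample_record):
    lib = ss.make_endmember_library(small_params.grid(), small_params)
    return ss.render_cube(sample_record, small_params, lib)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
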