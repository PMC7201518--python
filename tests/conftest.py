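import numpy as np
import pytest

from octaperf.synthetic import SimulationConfig, generate_vessel_tree, rasterize_angiogram


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(rng_seed=42)


@pytest.fixture(scope="session")
def sample_tree(default_config):
    return generate_vessel_tree(default_config)


@pytest.fixture(scope="session")
def sample_angiogram(sample_tree, default_config):
    return rasterize_angiogram(sample_tree, default_config, eye_id="fix", timepoint="pre")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
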