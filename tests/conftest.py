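import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from compsyn import CompetitionParams, SceneSpec, generate_doublet_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def noiseless_doublet():
    """One rendered two-neuron microisland with no noise or PSF."""
    spec = SceneSpec(n_cells=2)
    params = CompetitionParams((1.0, 1.0), 30, seed=11)
    images, gt = generate_doublet_scene(spec, params)
    return spec, params, images, gt


def random_binary_raster(rng, shape=(12, 12), p=0.4):
    return rng.random(shape) < p
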