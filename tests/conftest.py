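import numpy as np
import pytest

from laiscape import SceneConfig, generate_mosaic, simulate_lai


@pytest.fixture(scope="session")
def midseason_scene():
    """A moderate three-crop scene with LAI on a mid-season date."""
    cfg = SceneConfig(rows=400, cols=400, seed=123)
    truth = generate_mosaic(cfg)
    lai = simulate_lai(truth, cfg, 175)
    return cfg, truth, lai


@pytest.fixture
def rng():
    return np.random.default_rng(20160708)
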