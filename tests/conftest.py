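import numpy as np
import pytest

from camoquant import pipeline, synthetic


@pytest.fixture(scope="session")
def default_population():
    """Default-parameter synthetic population with derived metric columns."""
    pop = synthetic.generate_population(synthetic.PopulationParams(), seed=11)
    return pipeline.add_derived_columns(pop)


@pytest.fixture(scope="session")
def textured_scene():
    """One rendered scene with vegetation texture and moderate noise."""
    params = synthetic.SceneParams(vegetation_cover=0.45,
                                   gains=(1.2, 1.0, 0.8),
                                   pixel_noise_sd=0.005, seed=5)
    return synthetic.render_scene(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
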