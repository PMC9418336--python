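import numpy as np
import pytest

from smallfield import features, synthetic


@pytest.fixture(scope="session")
def scene():
    """Small synthetic scene without misregistration, shared across tests."""
    return synthetic.make_scene(96, seed=5, max_shift_px=0.0,
                                cloud_fraction=0.05)


@pytest.fixture(scope="session")
def series(scene):
    return synthetic.render_monthly_series(scene, noise_sd=0.03, seed=5)


@pytest.fixture(scope="session")
def stack(scene, series):
    return features.assemble_stack(series, scene.dem)


@pytest.fixture(scope="session")
def truth_codes(scene):
    return scene.class_map.codes


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
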