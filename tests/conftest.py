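import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gri_toolkit.raster_io import Grid
from gri_toolkit.synthetic_scene import SceneConfig, generate_scene

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    return Grid(x0=122.0, y0=46.0, dx=0.1, dy=0.1, shape=(4, 4))


@pytest.fixture(scope="session")
def scene_zero_noise():
    """Default 40x40, 22-year scene with no composite noise."""
    return generate_scene(SceneConfig(seed=20240001, noise_sd=0.0))


@pytest.fixture(scope="session")
def scene_noisy():
    """Default scene at the default composite noise level."""
    return generate_scene(SceneConfig(seed=20240002))
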