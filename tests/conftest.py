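import numpy as np
import pytest

from canopyhsi.io import HyperspectralCube, SpectralAxis
from canopyhsi.simulate import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def axis204() -> SpectralAxis:
    return SpectralAxis.linspace(400.0, 1000.0, 204)


@pytest.fixture(scope="session")
def mosaic_scene():
    """A small 14-class plot mosaic with background, fixed seed."""
    config = SceneConfig(height=48, width=48, seed=7)
    return generate_scene(config) + (config,)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_cube(rng) -> HyperspectralCube:
    axis = SpectralAxis(np.array([500.0, 600.0, 700.0, 800.0]))
    values = rng.random((3, 3, 4))
    return HyperspectralCube(values, axis)
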