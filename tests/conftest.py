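import numpy as np
import pytest

from phytoseg import SceneConfig, compute_stack, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """128x128 synthetic canopy scene with exact ground truth."""
    return generate_scene(SceneConfig(height=128, width=128, seed=7))


@pytest.fixture(scope="session")
def small_stack(small_scene):
    image, _ = small_scene
    return compute_stack(image)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
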