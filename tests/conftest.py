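import numpy as np
import pytest

import fundusqa as fq

SCENE_SEED = 1


@pytest.fixture(scope="session")
def default_scene():
    """Default synthetic fundus scene (512x512, seed-controlled)."""
    return fq.simulate_scene(seed=SCENE_SEED)


@pytest.fixture(scope="session")
def default_mask(default_scene):
    image, _ = default_scene
    return fq.segment_vessels(image.green)


@pytest.fixture(scope="session")
def default_report(default_scene):
    image, _ = default_scene
    return fq.analyze(image)


@pytest.fixture(scope="session")
def selftest_result():
    return fq.end_to_end_selftest(seed=SCENE_SEED)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, evenly illuminated variant of the default scene."""
    tree = fq.VesselTreeSpec(seed=SCENE_SEED)
    render = fq.RenderSpec(noise_sd=0.0, illumination_field_amplitude=0.0, seed=0)
    return fq.render_fundus(fq.generate_vessel_tree(tree), render)


@pytest.fixture(scope="session")
def small_bank():
    """Two-scale, four-orientation bank for brute-force comparisons."""
    return fq.build_kernel_bank(n_orient=4, sigmas=(1.0, 1.6), length_factor=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
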