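import numpy as np
import pytest

from mtcs import Scene, SceneSpec, TrackLayout, cube_to_matrix, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_scene(rng):
    """Small random cube: positive, no structure — exercises exact identities."""
    return Scene(values=rng.random((16, 16, 3)) + 0.01)


@pytest.fixture
def random_matrix(random_scene):
    return cube_to_matrix(random_scene)


@pytest.fixture
def two_track_layout(random_scene):
    return TrackLayout(random_scene.nh, random_scene.nw, 2)


@pytest.fixture
def mosaic_scene():
    return generate_scene(SceneSpec(kind="mosaic", nh=32, nw=32, nc=3,
                                    n_regions=4, intensity_scale=5e4, seed=7))


@pytest.fixture
def blob_scene():
    return generate_scene(SceneSpec(kind="blobs", nh=32, nw=32, nc=4,
                                    n_regions=3, intensity_scale=5e4, seed=9))


@pytest.fixture
def edge_image():
    """Two flat regions split at a non-dyadic column: every Haar scale has
    straddling (nonzero) detail coefficients at the boundary."""
    img = np.full((64, 64), 0.3)
    img[:, 27:] = 0.9
    return img
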