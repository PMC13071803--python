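import numpy as np
import pytest

from bvrpose.camera import make_camera
from bvrpose.phantom import NoiseSpec, make_scene, render_trial
from bvrpose.volume import centered_volume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def face_on_camera():
    """Camera looking straight down the +y axis at the world origin."""
    return make_camera(
        source=(0.0, -1000.0, 0.0),
        look_at=(0.0, 0.0, 0.0),
        up=(0.0, 0.0, 1.0),
        image_size=(65, 65),
        pixel_pitch_mm=1.0,
        source_to_detector_mm=1200.0,
    )


@pytest.fixture(scope="session")
def uniform_cube():
    """20 mm uniform attenuation cube centred on the origin."""
    mu = 0.02
    return centered_volume(np.full((20, 20, 20), mu, np.float32), 1.0), mu, 20.0


@pytest.fixture(scope="session")
def tiny_clean_scene():
    """Single-bone noiseless scene shared by registration tests."""
    scene = make_scene(
        bone_names=("talus",),
        image_size=(64, 64),
        volume_size=32,
        n_frames=1,
        noise=NoiseSpec(enabled=False),
        seed=3,
        soft_tissue=False,
        ct_blur_mm=0.0,
    )
    frames = render_trial(scene)
    return scene, frames
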