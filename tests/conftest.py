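import numpy as np
import pytest

from endospec import phantom
from endospec.rig import CameraRig


@pytest.fixture(scope="session")
def rig() -> CameraRig:
    """Default endoscope rig: f = 4.63 mm, baseline 4.16 mm, pitch 0.002 mm."""
    return CameraRig()


@pytest.fixture(scope="session")
def small_scene() -> phantom.PhantomScene:
    return phantom.make_scene(
        phantom.SceneConfig(seed=7, shape=(128, 384), cholesteatoma_fraction=0.3)
    )


@pytest.fixture(scope="session")
def small_render(small_scene, rig) -> phantom.StereoRender:
    return phantom.render_sequence(small_scene, rig)


@pytest.fixture(scope="session")
def calibration(small_scene) -> phantom.CalibrationFrames:
    return phantom.render_calibration_frames(shape=small_scene.shape)


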