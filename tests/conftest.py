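import numpy as np
import pytest

from glomflow import (
    Movie,
    RoiSet,
    StimulusEvent,
    StimulusProtocol,
    build_two_glomerulus_scene,
    simulate_movie,
)
from glomflow.synthetic import glomerulus_centroid, scene_roiset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_movie(rng):
    """A 20-frame 16x16 random movie at 5 Hz."""
    frames = rng.uniform(100, 200, size=(20, 16, 16))
    return Movie(frames=frames, frame_interval=0.2)


@pytest.fixture()
def two_roi_set():
    labels = np.zeros((16, 16), dtype=np.int32)
    labels[2:6, 2:6] = 1
    labels[10:14, 10:14] = 2
    return RoiSet(labels=labels, names={1: "left", 2: "right"})


@pytest.fixture()
def quiet_scene():
    """Noiseless two-glomerulus scene with zero coupling."""
    return build_two_glomerulus_scene(0, noise_sigma=0.0, coupling=0.0)


@pytest.fixture()
def quiet_recording(quiet_scene):
    """Noiseless movie with one suprathreshold stimulus on glomerulus 1."""
    target = glomerulus_centroid(quiet_scene.glomeruli[0])
    protocol = StimulusProtocol(
        events=(StimulusEvent(onset_time=10.0, duration=0.2, power=0.05, target=target),)
    )
    movie, truth = simulate_movie(quiet_scene, protocol, 40.0)
    return movie, truth, protocol, scene_roiset(quiet_scene)
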