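import numpy as np
import pytest

from octotrigger import default_settings, init_model
from octotrigger.frames import Frame
from octotrigger.imaging import crop_roi, gaussian_blur
from octotrigger.simulate import SceneRenderer, SceneSpec, TargetSpec


@pytest.fixture
def settings():
    return default_settings()


@pytest.fixture
def static_frames():
    """25 identical flat frames, the minimal burn-in sequence."""
    return [Frame(np.full((24, 32), 100, dtype=np.uint8)) for _ in range(25)]


@pytest.fixture
def burned_in_tei_model(settings):
    """MOG model burned in on 25 blurred-and-cropped static 320x240 TEIs."""
    bg = np.full((240, 320), 100, dtype=np.uint8)
    frames = [
        crop_roi(gaussian_blur(Frame(bg), 5), settings.motion.trigger_roi)
        for _ in range(settings.motion.frame_history)
    ]
    return init_model(frames, settings), bg


@pytest.fixture
def recovery_scene():
    """The standard target-recovery fixture: 25 background-only burn-in
    frames, then an ellipse of contrast 50 appears on frame 25."""
    scene = SceneSpec(duration_frames=26, seed=42)
    target = TargetSpec(
        a=20, b=10, contrast=50, entry_frame=25,
        start_center=(160.0, 120.0), velocity=(0.0, 0.0),
    )
    renderer = SceneRenderer(scene, [target])
    return scene, target, renderer
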