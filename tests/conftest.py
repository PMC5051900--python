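import numpy as np
import pytest

from microswim.imaging import ImagingConfig, render_sequence
from microswim.scenes import separated_dark_tracks
from microswim.sim import LightField, StimulusSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dark_schedule():
    return StimulusSchedule.constant((0, 0, 0, 0), 10.0)


@pytest.fixture
def default_field():
    return LightField()


@pytest.fixture
def wide_imaging_config():
    return ImagingConfig(frame_size=(1280, 960))


@pytest.fixture(scope="session")
def separated_tracks():
    """Ten mutually separated dark-swimming cells (ground truth v = 50 μm/s)."""
    tracks, _ = separated_dark_tracks(seed=42)
    return tracks


@pytest.fixture(scope="session")
def rendered_scene(separated_tracks):
    """simulate → render (noise 0): tracks plus their noise-free frame stack."""
    cfg = ImagingConfig(frame_size=(1280, 960))
    stack = render_sequence(separated_tracks, cfg, seed=7)
    return separated_tracks, stack, cfg
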