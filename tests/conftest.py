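import numpy as np
import pytest

from vibrotrack.scene_sim import MarkerSpec, SceneConfig, Tone
from vibrotrack.track import Calibration, make_template

PITCH = (0.49, 0.46)


def small_scene(**overrides) -> SceneConfig:
    """96x96 scene with one centered 8 mm cross; cheap enough for unit tests."""
    params = dict(
        width_px=96,
        height_px=96,
        fps=1000.0,
        duration_s=0.5,
        pixel_pitch_mm=PITCH,
        noise_sigma=0.0,
        texture_amp=0.05,
        markers=(MarkerSpec(center_px=(48.0, 48.0), arm_length_mm=8.0),),
        seed=0,
    )
    params.update(overrides)
    return SceneConfig(**params)


@pytest.fixture
def marker() -> MarkerSpec:
    return MarkerSpec(center_px=(48.0, 48.0), arm_length_mm=8.0)


@pytest.fixture
def template(marker):
    return make_template(marker, pixel_pitch_mm=PITCH, psf_sigma_px=0.7)


@pytest.fixture
def calibration() -> Calibration:
    return Calibration(*PITCH)


def tone(amplitude_um=2.5, frequency_hz=40.0, axis="horizontal", phase_rad=0.0) -> Tone:
    return Tone(amplitude_um, frequency_hz, phase_rad, axis)
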