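import numpy as np
import pytest

from pamharvest.detection import StftParams, build_template, detect_recording
from pamharvest.synthetic import GunshotSpec, SceneSpec, render_scene, synth_gunshot

SAMPLE_RATE = 8000


@pytest.fixture(scope="session")
def gun() -> GunshotSpec:
    return GunshotSpec()


@pytest.fixture(scope="session")
def stft_params() -> StftParams:
    return StftParams()


@pytest.fixture(scope="session")
def template(gun, stft_params):
    """Matched template averaged over clean exemplar pulses at three distances."""
    clips = [synth_gunshot(gun, d, SAMPLE_RATE) for d in (100.0, 200.0, 400.0)]
    return build_template(clips, SAMPLE_RATE, gun.duration_s,
                          (gun.band_low_hz, gun.band_high_hz), stft_params)


@pytest.fixture(scope="session")
def detected_scene(gun, template, stft_params):
    """A 66 s scene with 10 well-separated shots, plus its detections."""
    events = [(5.0 + 6.0 * i, 300.0) for i in range(10)]
    scene = SceneSpec(duration_s=66.0, noise_rms=0.005, events=events, seed=3)
    audio, truth = render_scene(scene, gun)
    detections = detect_recording(audio, template, 0.4, 0.5, stft_params)
    return scene, audio, truth, detections
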