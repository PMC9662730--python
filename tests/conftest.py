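import numpy as np
import pytest

from spectrotex.config import config_from_dict
from spectrotex.io import RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """16-channel, 10 s recording at 256 Hz with standard channel names."""
    from spectrotex.io import STANDARD_16_CHANNELS

    data = rng.normal(0, 20, (16, 2560))
    return RawRecording(data=data, fs=256.0,
                        channel_names=list(STANDARD_16_CHANNELS),
                        label="HC", subject_id="S00")


@pytest.fixture
def tiny_config():
    """A three-class, well-separated synthetic study small enough for
    seconds-scale end-to-end tests."""
    return config_from_dict({
        "synth": {
            "n_subjects": 2,
            "seconds_per_subject": 9.0,
            "classes": [
                {"name": "A", "band_centers_hz": [8.0], "band_powers": [1.0]},
                {"name": "B", "band_centers_hz": [20.0], "band_powers": [1.0]},
                {"name": "C", "band_centers_hz": [32.0], "band_powers": [1.0]},
            ],
        },
        "seed": 7,
    })


def random_images(rng, n, shape):
    """Uniform-random uint8 test images."""
    return [rng.integers(0, 256, shape).astype(np.uint8) for _ in range(n)]
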