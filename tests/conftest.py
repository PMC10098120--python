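import numpy as np
import pytest

from spindlefusion.io import RunConfig
from spindlefusion.model import Recording
from spindlefusion.synth import CohortParams, gen_subject


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_params():
    return CohortParams(channels=("C3",), duration_min=20.0)


@pytest.fixture(scope="session")
def small_subject(small_params):
    """One rendered 20-min single-channel subject (recording, truth,
    hypnogram, record); the fixed-seed subject used across detector tests."""
    return gen_subject(small_params, "NS", seed=7, subject_index=0)


def make_recording(signal, rate=256.0, channel="C3", subject_id="T1"):
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    return Recording(
        subject_id=subject_id,
        channel_labels=(channel,),
        sampling_rate=rate,
        samples=sig,
    )


@pytest.fixture
def sine_recording():
    """10 s of a pure 13 Hz sine, peak amplitude 20 uV, at 256 Hz."""
    t = np.arange(0, 10 * 256) / 256.0
    return make_recording(20.0 * np.sin(2 * np.pi * 13.0 * t))
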