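import numpy as np
import pytest

from gaitshotgun.synthetic import generate_gait_recording, study_a_spec, study_b_spec


@pytest.fixture(scope="session")
def gait_recording():
    """One two-minute single-group recording with ground truth."""
    spec = study_a_spec(duration_s=120.0)
    rec, truth = generate_gait_recording(spec, seed=1)
    return spec, rec, truth


@pytest.fixture(scope="session")
def emg_recording():
    """A shorter recording that includes the five-muscle EMG montage."""
    spec = study_b_spec(duration_s=45.0)
    rec, truth = generate_gait_recording(spec, seed=2, include_emg=True)
    return spec, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
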