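import numpy as np
import pytest

from facemms.preprocessing import default_partition
from facemms.synthetic_cohort import default_profiles, generate_recording


@pytest.fixture(scope="session")
def partition():
    return default_partition()


@pytest.fixture(scope="session")
def td_recording():
    """One seeded resting recording from the default TD profile."""
    return generate_recording(default_profiles()["TD"], "resting", seed=7)


@pytest.fixture(scope="session")
def asd_recording():
    return generate_recording(default_profiles()["ASD-HS"], "resting", seed=11)


@pytest.fixture(scope="session")
def td_speed(td_recording, partition):
    from facemms.preprocessing import compute_speed, zscore_frames

    return compute_speed(zscore_frames(td_recording), partition)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
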