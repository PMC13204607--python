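import numpy as np
import pytest

from dsp_spiro import (DetectionParams, SimulationConfig, detect_phases,
                       simulate_session, simulate_subject_profiles)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    return SimulationConfig(n_subjects=1, seed=0, snr_db=30.0)


@pytest.fixture(scope="session")
def clean_session(clean_config):
    """One clean forceful session with 5 annotated cycles."""
    profile = simulate_subject_profiles(clean_config)[0]
    return simulate_session(profile, "forceful", 5, clean_config, seed=42)


@pytest.fixture(scope="session")
def clean_detection(clean_session):
    return detect_phases(clean_session, DetectionParams())
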