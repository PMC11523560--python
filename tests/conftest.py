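import numpy as np
import pytest

from fatiguetl.anthropometry import (GENERIC_ACTUATORS, REFERENCE,
                                     SubjectStatics, scale_model)
from fatiguetl.benchmark import BenchmarkConfig, build_simulated_trials
from fatiguetl.fatigue import FatigueParams
from fatiguetl.synthrec import SessionConfig, generate_session


@pytest.fixture(scope="session")
def ref_subject():
    return REFERENCE.reference_statics


@pytest.fixture(scope="session")
def ref_model(ref_subject):
    return scale_model(GENERIC_ACTUATORS, ref_subject)


@pytest.fixture(scope="session")
def small_sim_trials():
    """A handful of simulated trials (3 subjects x 7 peaks, minus failures)."""
    return build_simulated_trials(BenchmarkConfig(n_sim_subjects=3), seed=0)


@pytest.fixture(scope="session")
def default_session(ref_subject):
    return generate_session(ref_subject, FatigueParams(), SessionConfig(),
                            seed=42)


@pytest.fixture(scope="session")
def clean_session_config():
    """Session generator with every stochastic disturbance switched off."""
    return SessionConfig(mvc_noise_sd=1e-12, torque_noise_sd=1e-12,
                         emg_baseline_sd=0.0, emg_dc_offset=0.0,
                         emg_drift=0.0, emg_envelope_jitter_sd=0.0,
                         effort_wander_sd=0.0, fatigue_rate_jitter_sd=1e-12)
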