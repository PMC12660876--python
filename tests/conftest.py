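import numpy as np
import pytest

import probcode as pc
from probcode.simulate import generate_participant_sessions


@pytest.fixture(scope="session")
def task_config():
    return pc.TaskConfig()


@pytest.fixture(scope="session")
def obs_config(task_config):
    return pc.ObserverConfig.default(task_config.p_support,
                                     hazard=task_config.hazard)


@pytest.fixture(scope="session")
def participant_sessions(task_config, obs_config):
    """One simulated participant's sessions (no voxel data attached).

    Session scope: sequence generation and observer runs are deterministic
    given the seed, and tests only read from it (voxel data is attached to
    per-test copies).
    """
    rng = np.random.default_rng(12345)
    return generate_participant_sessions(task_config, obs_config, rng)


@pytest.fixture()
def sessions_with_data(participant_sessions):
    """Per-test shallow copies so tests can attach their own y safely."""
    from probcode.design import SessionData
    return [SessionData(seq=s.seq, trace=s.trace, est=s.est, reports=s.reports)
            for s in participant_sessions]


@pytest.fixture(scope="session")
def short_task_config():
    """A miniature task for fast design/evaluation tests."""
    return pc.TaskConfig(n_stimuli_per_session=60, report_mean_interval=15,
                         report_jitter=2)
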