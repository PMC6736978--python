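import numpy as np
import pytest

from standshift import SimConfig, VirtualParticipant, simulate_session


@pytest.fixture(scope="session")
def short_quiet_session():
    """A short, noise-free, fully habituated session for closed-loop checks."""
    p = VirtualParticipant(
        habituation=0.0,
        force_noise_sd=0.0,
        marker_noise_sd=0.0,
        cycle_jitter_sd=0.0,
        session_jitter_sd=0.0,
    )
    cfg = SimConfig(seed=7, duration=240.0)
    return p, cfg, simulate_session(p, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
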