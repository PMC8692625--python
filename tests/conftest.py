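import numpy as np
import pytest

import bedvitals as bv


@pytest.fixture(scope="session")
def quiet_night():
    """10-minute single-person session: 15 bpm breathing, 65 bpm heart."""
    frame, truth = bv.simulate_session(
        [bv.PersonSpec(resp_rate=15, heart_rate=65)],
        noise_sd=0.01, duration_s=600.0, seed=101)
    return frame, truth


@pytest.fixture(scope="session")
def two_sleepers():
    """10-minute two-person session with independent leg projections."""
    p1 = bv.PersonSpec(weight=160, resp_rate=12, heart_rate=60,
                       projection=(0.4, 0.3, 0.2, 0.1), label="P1")
    p2 = bv.PersonSpec(weight=125, resp_rate=17, heart_rate=75,
                       projection=(0.1, 0.2, 0.3, 0.4), label="P2")
    frame, truth = bv.simulate_session([p1, p2], noise_sd=0.02,
                                       duration_s=600.0, seed=202)
    return frame, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
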