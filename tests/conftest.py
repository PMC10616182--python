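import numpy as np
import pandas as pd
import pytest

import refrep as rr


@pytest.fixture(scope="session")
def paper_params():
    """Generative observer in the study regime (see refrep.observer)."""
    return rr.DEFAULT_OBSERVER


@pytest.fixture(scope="session")
def session_trials():
    """One participant-scale design: 5 single + 5 dual blocks, 1560 trials."""
    return rr.generate_session(5, 5, seed=11)


@pytest.fixture(scope="session")
def pooled_data(paper_params):
    """Pooled-scale simulated dataset: five sessions, 7800 trials."""
    frames = [
        rr.simulate_session(rr.generate_session(5, 5, seed=100 + i), paper_params, seed=200 + i)
        for i in range(5)
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_data(paper_params, session_trials):
    """One simulated session (1560 trials)."""
    return rr.simulate_session(session_trials, paper_params, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
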