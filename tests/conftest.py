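import numpy as np
import pytest

import anwc
from anwc import synthetic_athlete as sa


@pytest.fixture(scope="session")
def noise_free():
    """One noise-free synthetic athlete: (session, truth)."""
    params = sa.SyntheticAthleteParams(noise_cv_vo2=0.0)
    return sa.simulate_full_session(params, seed=1)


@pytest.fixture(scope="session")
def noise_free_result(noise_free):
    session, _ = noise_free
    return anwc.run_pipeline(session)


@pytest.fixture
def rng():
    return np.random.default_rng(20220917)
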