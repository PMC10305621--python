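import pytest

from clmscreen.synthetic_data import make_study_fixture, simulate_study


@pytest.fixture(scope="session")
def study_fixture():
    return make_study_fixture()


@pytest.fixture(scope="session")
def noiseless_readouts(study_fixture):
    """Pooled + control readouts at 4 h and 24 h without measurement noise."""
    return simulate_study(study_fixture, times=(4.0, 24.0), noise_sd=0.0, seed=0)
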