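import pytest

from locomod.preprocess import balance_trials, extract_trial_responses
from locomod.synthgen import SessionConfig, generate_session


@pytest.fixture(scope="session")
def gap_bundle():
    """One moderate reliability-gap session shared by read-only tests."""
    cfg = SessionConfig(n_neurons=60, n_reps=30, spont_s=60.0)
    return generate_session(cfg, seed=11)


@pytest.fixture(scope="session")
def gap_trials(gap_bundle):
    return balance_trials(extract_trial_responses(gap_bundle), seed=0)
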