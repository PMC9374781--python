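import numpy as np
import pytest

from gamblearn import models, task


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def decks():
    return task.build_decks(0.30)


@pytest.fixture(scope="session")
def model6_log():
    """One deterministic-seed session of an adjusted-asymmetric agent."""
    r = np.random.default_rng(99)
    params = dict(bias=0.1, beta_number=2.0, beta_value=2.0,
                  eta_pos=0.45, eta_neg=0.25)
    return models.simulate_agent(6, params, rng=r)


def make_log(trials, subject_id="t", session=1):
    """Assemble a SessionLog from (deck, N, choice, outcome) tuples."""
    log = task.SessionLog(subject_id=subject_id, session=session)
    for i, (deck, n, choice, outcome) in enumerate(trials, start=1):
        log.trials.append(task.TrialRecord(
            session=session, trial_index=i,
            block=int(np.ceil(i / task.BLOCK_SIZE)), deck=deck,
            computer_number=n, choice=choice, outcome=outcome,
            outcome_shown=choice == 1))
    return log
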