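import numpy as np
import pytest

import rbdkit as rk


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete two-group cohort for structural tests."""
    cfg = rk.CohortConfig(n_mdd=30, n_hc=12, rng_seed=42)
    sessions, demographics = rk.simulate_cohort(cfg)
    return cfg, sessions, demographics


@pytest.fixture
def toy_session():
    """Hand-built 8-trial session with a known tally.

    Block 1: rich trials RRRL-responses -> 3 rich-correct, 1 rich-incorrect;
    lean trials: 1 lean-correct, 1 lean-incorrect.  Block 2: 1 rich-correct,
    1 lean-correct.
    """
    mk = rk.TrialRecord
    trials = [
        mk("T1", "MDD", 1, 1, "rich", "rich", True, True),
        mk("T1", "MDD", 1, 2, "rich", "rich", True, False),
        mk("T1", "MDD", 1, 3, "rich", "rich", True, False),
        mk("T1", "MDD", 1, 4, "rich", "lean", False, False),
        mk("T1", "MDD", 1, 5, "lean", "lean", True, True),
        mk("T1", "MDD", 1, 6, "lean", "rich", False, False),
        mk("T1", "MDD", 2, 1, "rich", "rich", True, False),
        mk("T1", "MDD", 2, 2, "lean", "lean", True, False),
    ]
    return rk.SubjectSession(subject_id="T1", group="MDD", trials=trials)


@pytest.fixture
def default_payoff():
    return rk.PayoffStructure()


def random_payoff(rng: np.random.Generator) -> rk.PayoffStructure:
    """A random but valid asymmetric payoff structure."""
    p_lean = rng.uniform(0.05, 0.45)
    return rk.PayoffStructure(
        reward_cents=rng.uniform(5, 50),
        p_reward_given_correct_rich=min(1.0, p_lean * rng.uniform(1.5, 4.0)),
        p_reward_given_correct_lean=p_lean,
        stimulus_probability_rich=rng.uniform(0.2, 0.8),
    )
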