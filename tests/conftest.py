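import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from socialfeedback import (
    CohortConfig,
    aggregate_condition_scores,
    simulate_cohort_trials,
)
from socialfeedback.task import FEEDBACK_GRID


@pytest.fixture(scope="session")
def default_cohort():
    """One default-calibration cohort, shared across tests."""
    trials, participants = simulate_cohort_trials(CohortConfig(rng_seed=42))
    return trials, participants


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    trials, participants = default_cohort
    return aggregate_condition_scores(trials), participants


def random_trial_table(rng: np.random.Generator, n_participants=4, n_trials=40,
                       missing_rate=0.05) -> pd.DataFrame:
    """A random schema-valid trial table, independent of the simulator."""
    rows = []
    for p in range(n_participants):
        for i in range(n_trials):
            first = rng.integers(1, 9)
            second = rng.integers(1, 9)
            rows.append(
                {
                    "participant_id": f"s{p}",
                    "run": int(1 + i % 4),
                    "order_index": i,
                    "target": rng.choice(["self", "other"]),
                    "adjective": f"adj{i}",
                    "valence": rng.choice(["positive", "negative"]),
                    "first_rating": np.nan if rng.random() < missing_rate else float(first),
                    "feedback": float(rng.choice(FEEDBACK_GRID)),
                    "second_rating": np.nan if rng.random() < missing_rate else float(second),
                    "recollection": np.nan
                    if rng.random() < missing_rate
                    else float(rng.choice(FEEDBACK_GRID)),
                }
            )
    return pd.DataFrame(rows)
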