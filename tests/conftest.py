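import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import abmtrial as ab

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def alloc100():
    return ab.allocate_blocks(100, seed=1)


@pytest.fixture(scope="session")
def small_cohort(alloc100):
    """Default-model synthetic cohort: trials, cleaned trials, report, scores."""
    trials = ab.generate_trials(alloc100, ab.RtGenModel(), seed=2)
    cleaned, report = ab.clean_trials(trials)
    scores = ab.generate_scores(alloc100, ab.ScoreGenModel(), seed=3, with_items=True)
    return {"alloc": alloc100, "trials": trials, "cleaned": cleaned,
            "report": report, "scores": scores}


def make_trials(rows):
    """Build a trials frame from (pid, timepoint, trial_type, correct, rt) tuples."""
    df = pd.DataFrame(rows, columns=["participant_id", "timepoint", "trial_type", "correct", "rt_ms"])
    df["discarded"] = False
    df["discard_reason"] = "none"
    return df


@pytest.fixture
def trials_factory():
    return make_trials
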