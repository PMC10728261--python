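import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trialnoise.trial_data import TrialTable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_table(rows):
    """Build a TrialTable from (person, task, condition, rt) tuples."""
    return TrialTable(
        pd.DataFrame(rows, columns=["person", "task", "condition", "rt"])
    )


@pytest.fixture
def toy_table():
    """1 person, 1 task, 4 congruent + 4 incongruent trials."""
    rows = [
        ("p1", "stroop", "congruent", 300.0),
        ("p1", "stroop", "congruent", 320.0),
        ("p1", "stroop", "congruent", 310.0),
        ("p1", "stroop", "congruent", 330.0),
        ("p1", "stroop", "incongruent", 350.0),
        ("p1", "stroop", "incongruent", 370.0),
        ("p1", "stroop", "incongruent", 360.0),
        ("p1", "stroop", "incongruent", 380.0),
    ]
    return make_table(rows)


@pytest.fixture
def two_person_table():
    """2 persons x 1 task, 2 trials per condition each."""
    rows = []
    for p, (c_rts, i_rts) in {
        "p1": ([300.0, 320.0], [350.0, 370.0]),
        "p2": ([400.0, 420.0], [420.0, 440.0]),
    }.items():
        rows += [(p, "stroop", "congruent", rt) for rt in c_rts]
        rows += [(p, "stroop", "incongruent", rt) for rt in i_rts]
    return make_table(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
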