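import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from itemlens import (
    AbilitySpec,
    ScoredMatrix,
    fit_interaction,
    fit_rasch_cml,
    score_responses,
    simulate_choices,
    simulate_rasch,
    spm01_exercise_scenario,
)

# 4 persons x 3 binary items used throughout the CTT unit tests
TOY_SCORES = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0], [1, 1, 1]])

TRUE_BETA_12 = np.linspace(-2.0, 2.0, 12)


@pytest.fixture
def toy_matrix():
    return ScoredMatrix(
        persons=[f"p{k}" for k in range(4)],
        items=["i1", "i2", "i3"],
        scores=TOY_SCORES,
        max_score=[1, 1, 1],
    )


@pytest.fixture(scope="session")
def rasch_data():
    """Binary Rasch simulation: I = 12, beta spaced -2..2, theta ~ N(0,1), P = 3000."""
    mat = simulate_rasch(TRUE_BETA_12, AbilitySpec(n_persons=3000), seed=20240501)
    return TRUE_BETA_12, mat


@pytest.fixture(scope="session")
def rasch_fit(rasch_data):
    return fit_rasch_cml(rasch_data[1])


@pytest.fixture(scope="session")
def im_fit(rasch_data):
    return fit_interaction(rasch_data[1])


@pytest.fixture(scope="session")
def spm01_run():
    """Raw-choice data with the exercise-item pathology planted in item01."""
    records, rules, _ = simulate_choices(
        spm01_exercise_scenario(), AbilitySpec(n_persons=3000), seed=11
    )
    matrix = score_responses(records, rules)
    return records, rules, matrix


@pytest.fixture(scope="session")
def spm01_im(spm01_run):
    return fit_interaction(spm01_run[2])
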