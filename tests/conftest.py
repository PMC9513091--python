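import numpy as np
import pytest

from taskdelay.discounting import DiscountParams
from taskdelay.synthetic_data import (
    PopulationSpec,
    generate_choice_set,
    generate_population,
    simulate_choices,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Five synthetic participants with default population settings."""
    return generate_population(PopulationSpec(n_participants=5, seed=11))


@pytest.fixture(scope="session")
def participant(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def reward_choices(participant):
    """120 reward-domain choices simulated under the participant's truth."""
    trials = generate_choice_set(participant, "reward", n_trials=120, seed=21)
    return simulate_choices(trials, participant.true_params, seed=22)


@pytest.fixture(scope="session")
def all_category_choices(participant):
    trials = []
    for j, cat in enumerate(("reward", "effort", "punishment")):
        cs = generate_choice_set(participant, cat, n_trials=120, seed=31 + j)
        trials += simulate_choices(cs, participant.true_params, seed=41 + j)
    return trials
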