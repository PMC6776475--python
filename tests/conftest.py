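import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sugarintake.composition import build_database
from sugarintake.intake import intake_summaries, nutrient_frame
from sugarintake.simulate import gen_food_db, simulate_study


@pytest.fixture(scope="session")
def food_db():
    """Synthetic food table, its engine assignments and the hidden ground truth."""
    items, truth = gen_food_db(seed=0)
    return items, build_database(items), truth


@pytest.fixture(scope="session")
def study():
    """One default-configuration synthetic study (n = 332), fully generated."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def study_summaries(study):
    """Per-child intake summaries of the session study."""
    nutrients = nutrient_frame(study.food_items, study.assignments)
    return intake_summaries(study.records, nutrients)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
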