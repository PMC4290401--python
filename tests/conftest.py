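import numpy as np
import pandas as pd
import pytest

import natri


def make_cohort(**overrides):
    """Generate a filtered cohort (demo with age groups, recalls, truth)."""
    cfg = natri.SimConfig(**overrides)
    demo, recalls, truth = natri.generate_cohort(cfg)
    demo = natri.assign_age_groups(natri.apply_population_filters(demo))
    recalls = recalls[recalls["person_id"].isin(demo["person_id"])].reset_index(drop=True)
    return cfg, demo, recalls, truth


NOISE_FREE_KW = dict(
    sigma_within=0.0, beta_weekend=0.0, beta_sequence=0.0, p_weekend=0.0,
    dirichlet_concentration=None, toddler_rate=0.0, pregnancy_rate=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(n_persons=300, seed=5)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic day totals; food group 1 carries exactly 28% of sodium."""
    comp = (0.28, 0.12, 0.05, 0.05, 0.20, 0.05, 0.10, 0.05, 0.10)
    return make_cohort(n_persons=300, seed=3, group_composition=comp,
                       **NOISE_FREE_KW)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The parameter-recovery study condition: n=2000, lognormal model."""
    return make_cohort(n_persons=2000, seed=7)


@pytest.fixture
def group1_scenario():
    """All foods of group 1 at a uniform 25% maximum reduction."""
    codes = [natri.simulate.food_code(1, i) for i in range(4)]
    return natri.Scenario(reductions=pd.Series(0.25, index=pd.Index(codes, name="food_code"),
                                               name="max_reduction_fraction"))
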