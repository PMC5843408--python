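import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1_cohort():
    """Small static-paradigm cohort with SCRs and ratings attached."""
    from relieflearn.pipeline import (attach_ratings, attach_scr,
                                      simulate_td_cohort)
    cohort = simulate_td_cohort(n_subjects=4, seed=101, paradigm="exp1")
    attach_scr(cohort, seed=102, bilateral=False)
    attach_ratings(cohort, seed=103)
    return cohort


@pytest.fixture(scope="session")
def exp2_cohort():
    """Small dynamic-paradigm cohort with bilateral SCRs and ratings."""
    from relieflearn.pipeline import (attach_ratings, attach_scr,
                                      simulate_td_cohort)
    cohort = simulate_td_cohort(n_subjects=4, seed=201)
    attach_scr(cohort, seed=202)
    attach_ratings(cohort, seed=203)
    return cohort
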