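import numpy as np
import pandas as pd
import pytest

import gnet


@pytest.fixture(scope="session")
def pool():
    return gnet.generate_pool(seed=1)


@pytest.fixture(scope="session")
def scores(pool):
    return gnet.compute_indices(pool)


@pytest.fixture(scope="session")
def zscores(scores):
    """Difference indices z-scored across the pool, matching the scale the
    simulator's slopes are expressed on."""
    z = scores.copy()
    for c in ("dtf", "dtaf", "dtan"):
        x = z[c].astype(float)
        z[c] = (x - x.mean()) / x.std(ddof=0)
    return z


@pytest.fixture(scope="session")
def sched(pool):
    return gnet.build_schedule(pool, seed=2)


@pytest.fixture(scope="session")
def cohort_log(pool, scores):
    """A small simulated cohort shared by analysis tests."""
    cohort = gnet.CohortParams(n_participants=30, seed=11)
    log, scheds = gnet.simulate_cohort(pool, cohort, scores, index="dtf")
    return log, scheds, cohort
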