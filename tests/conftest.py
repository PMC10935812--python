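import numpy as np
import pandas as pd
import pytest

import linksurv as ls
from linksurv.cohort import LinkedCohort


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def setting1_cohort():
    """One drawn cohort under the MCAR benchmark setting."""
    return ls.draw_cohort(ls.load_setting(1, seed=123))


@pytest.fixture
def tiny_cohort():
    """Hand-built 4-record cohort: unequivocal, equivocal (p=0.6),
    nonmatch, unequivocal."""
    df = pd.DataFrame(
        {
            "id": ["a", "b", "c", "d"],
            "x": [1, 0, 1, 0],
            "z": [0, 1, 1, 0],
            "w": [30.0, 40.0, 35.0, 20.0],
            "v": [80.0, 90.0, 85.0, 70.0],
            "r": [1, 1, 0, 1],
            "p_match": [0.95, 0.6, 0.0, 0.9],
            "t_star": [62.0, 71.5, np.nan, 55.0],
        }
    )
    return LinkedCohort(df)


def uncensored_weibull_set(alpha, shape_p, n, seed):
    """Analysis set of fully-observed Weibull AFT lifetimes (no censoring)."""
    g = np.random.default_rng(seed)
    x = g.integers(0, 2, n)
    z = g.integers(0, 2, n)
    mu = alpha[0] + alpha[1] * x + alpha[2] * z
    t = np.exp(mu) * g.exponential(size=n) ** (1.0 / shape_p)
    return ls.make_analysis_set(time=t, event=np.ones(n, dtype=int),
                                weight=np.ones(n), x=x, z=z, source="sim")
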