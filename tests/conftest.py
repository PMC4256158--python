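import numpy as np
import pandas as pd
import pytest

import wormdemog as w


def make_events(rows):
    """Build an event table from (id, group, replicate, day, status) tuples."""
    return pd.DataFrame(
        rows, columns=["individual_id", "group", "replicate", "event_day", "status"]
    )


@pytest.fixture
def toy_events():
    """Four worms: deaths on days {1, 1, 2}, one censored on day 2.

    Hand enumeration: day 1 has N=4, d=2, q=0.5; day 2 has N=2, d=1, c=1,
    q=0.5; KM(1)=0.5, KM(2)=0.25.
    """
    return make_events(
        [
            ("a", "g", "r1", 1, "death"),
            ("b", "g", "r1", 1, "death"),
            ("c", "g", "r1", 2, "death"),
            ("d", "g", "r1", 2, "censored"),
        ]
    )


@pytest.fixture
def simulated_cohort():
    """One 200-worm cohort with 10%/day censoring from known GM parameters."""
    params = w.GMParams(m0=0.004, g=0.25)
    times = w.sample_gm_lifetimes(params, 200, seed=123)
    return w.discretize_and_censor(times, censor_prob_per_day=0.01, max_day=60, seed=456)
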