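import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import eclorhythm as er
from eclorhythm.synthetic_data import clockless, wildtype_gated

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def season():
    return er.SeasonSpec()


@pytest.fixture(scope="session")
def environment(season):
    return er.simulate_environment(season, seed=42)


@pytest.fixture(scope="session")
def gated_profile(environment):
    """A strongly gated 5-day cohort, binned hourly."""
    events, _ = er.simulate_cohort(
        er.CohortSpec(n_flies=400, seed=7), wildtype_gated(), environment, seed=7
    )
    return er.bin_hourly(events)


@pytest.fixture(scope="session")
def gatefree_profile(environment):
    events, _ = er.simulate_cohort(
        er.CohortSpec(n_flies=400, seed=8), clockless(), environment, seed=8
    )
    return er.bin_hourly(events)


@pytest.fixture
def cosine_profile():
    """Noiseless 24-h cosine over 6 days, offset so counts stay non-negative."""
    t = np.arange(144)
    y = np.round(50 + 30 * np.cos(2 * np.pi * t / 24)).astype(int)
    return er.HourlyProfile(
        experiment_id="cosine", start=pd.Timestamp("2015-06-01 00:00"), counts=y
    )


def hourly_profile_from_counts(counts, start="2015-06-01 00:00", experiment_id="t"):
    return er.HourlyProfile(
        experiment_id=experiment_id, start=pd.Timestamp(start),
        counts=np.asarray(counts, dtype=np.int64),
    )
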