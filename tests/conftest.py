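import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tickabund as ta

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def small_config(seed=0, **kwargs):
    """Reduced study design (~350 rows) for fast fitting in tests."""
    return ta.default_config(seed=seed, years=(2009, 2011), **kwargs)


@pytest.fixture(scope="session")
def small_panel():
    panel, latents = ta.simulate_panel(small_config(seed=42))
    return panel, latents


@pytest.fixture(scope="session")
def nb_fit_small(small_panel):
    panel, _ = small_panel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ta.fit(panel, ta.ModelSpec(family="nb", draws=300, seed=1))


@pytest.fixture()
def toy_records():
    return pd.DataFrame({
        "location": ["A", "A", "A", "B", "B", "B"],
        "habitat": ["Edge", "edge", "grass", "woods", "woods", "grass"],
        "year": [2010, 2010, 2010, 2010, 2010, 2011],
        "month": [4, 4, 5, 4, 5, 1],
        "larvae": [3, 2, 0, 10, 4, 1],
        "nymphs": [1, 0, 2, 5, 0, 0],
        "adults": [0, 1, 0, 2, 1, 3],
    })


def rng(seed=0):
    return np.random.default_rng(seed)
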