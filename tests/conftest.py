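import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phewaskit.phenome_map import load_fixture_map
from phewaskit.synthetic_data import SimConfig, generate_study

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_map():
    return load_fixture_map()


@pytest.fixture(scope="session")
def small_study():
    """Small two-cohort study reused across tests (deterministic, seed 7)."""
    cfg = SimConfig(n_per_cohort=(600, 500), seed=7, n_null_phenotypes=4)
    return generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def events_frame(rows):
    """rows: iterable of (person_id, date, icd9)."""
    return pd.DataFrame(rows, columns=["person_id", "date", "icd9"])
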