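import numpy as np
import pandas as pd
import pytest

from chronogut.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic cohort (all tables) shared across
    tests that only read from it."""
    cfg = SyntheticConfig(
        n_participants=160,
        n_species=40,
        n_direct_species=4,
        n_mediated_species=1,
        cgm_days=2,
        n_meal_days=2,
        n_negative_sjl=3,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def core_bundle():
    """Core tables only (no meal/CGM/postprandial), mid-sized cohort."""
    cfg = SyntheticConfig(n_participants=400, n_species=60, seed=21)
    return generate_cohort(cfg, include=())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sjl_series(bundle) -> pd.Series:
    return pd.Series(bundle.ground_truth["sjl_status"])
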