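import numpy as np
import pandas as pd
import pytest

from hrvequiv import impute, simulate
from hrvequiv.preprocessing import HeartPeriodSeries


@pytest.fixture(scope="session")
def clean_series() -> HeartPeriodSeries:
    """A realistic clean 5-min resting recording."""
    return simulate.simulate_hp_series(simulate.HPSimConfig(seed=7))


@pytest.fixture(scope="session")
def constant_series() -> HeartPeriodSeries:
    return HeartPeriodSeries.from_intervals([800.0] * 380)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return simulate.simulate_cohort(
        simulate.CohortSimConfig(n_per_country=80, seed=42)
    )


@pytest.fixture(scope="session")
def cohort_with_missing() -> pd.DataFrame:
    return simulate.simulate_cohort(
        simulate.CohortSimConfig(
            n_per_country=80, seed=43, missing_rate=0.02, missing_mechanism="MCAR"
        )
    )


@pytest.fixture(scope="session")
def imputed_small(cohort_with_missing):
    cfg = impute.ImputationConfig(m=2, maxit=2, seed=99)
    return impute.chained_impute(cohort_with_missing, cfg)


def rmssd_bruteforce(hp) -> float:
    """Independent two-line reference for the RMSSD formula."""
    hp = list(map(float, hp))
    n = len(hp)
    return (sum((hp[i] - hp[i - 1]) ** 2 for i in range(1, n)) / (n - 1)) ** 0.5


@pytest.fixture(scope="session")
def rmssd_oracle():
    return rmssd_bruteforce
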