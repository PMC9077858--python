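import warnings

import numpy as np
import pandas as pd
import pytest

import pedsep
from pedsep import screening, simulate

# the copula / solver warnings from scipy are noise in test output
warnings.filterwarnings("ignore", category=RuntimeWarning,
                        module="scipy")


def make_day(day=1, first_6h=False, **overrides) -> dict:
    """One healthy patient-day record; override fields to trip rules."""
    base = {
        "patient_id": "P1", "day": day, "first_6h": first_6h,
        "temperature_low": 36.8, "temperature_high": 37.4,
        "heart_rate": 110.0, "systolic_bp": 100.0, "gcs": 15.0,
        "hemoglobin": 12.0, "platelets": 250.0, "inr": 1.0, "alc": 2.0,
        "crp": 2.0, "ferritin": 80.0, "creatinine": 0.4, "alt": 25.0,
        "bilirubin": 0.3, "pf_ratio": 400.0, "urine_output": 2.0,
        "on_vasoactive": 0.0, "intubated": 0.0, "mech_vent": 0.0,
        "sedated": 0.0, "tnf_response": 600.0, "adamts13": 100.0,
        "sfasl": 50.0, "wbc": 9.0, "resp_rate": 20.0,
    }
    base.update(overrides)
    return base


def make_series(*day_dicts) -> pd.DataFrame:
    return pd.DataFrame(list(day_dicts))


@pytest.fixture(scope="session")
def default_config():
    return pedsep.SimConfig.default(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return simulate.generate_cohort(default_config)


@pytest.fixture(scope="session")
def observed_cohort(default_cohort):
    return simulate.inject_missingness(default_cohort)


@pytest.fixture(scope="session")
def candidate_table(observed_cohort):
    table, flags = simulate.make_candidate_table(observed_cohort)
    return table, flags


@pytest.fixture(scope="session")
def screened(candidate_table):
    table, _ = candidate_table
    report = screening.screen_variables(table,
                                        schema_order=list(table.columns))
    return table, report


@pytest.fixture(scope="session")
def cohort_matrix(screened):
    table, report = screened
    full, _ = screening.impute(table[report.retained])
    return screening.transform_standardize(full)


@pytest.fixture(scope="session")
def latent_truth(default_cohort):
    return default_cohort.truth.set_index("patient_id")["latent_phenotype"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220507)
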