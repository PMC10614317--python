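import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from incrisk import CohortTable, DataDictionary, default_params, dictionary_for_params, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_params():
    return default_params()


@pytest.fixture(scope="session")
def study_cohort(study_params):
    """One default-sized synthetic cohort (n=561) as a validated CohortTable."""
    return CohortTable(generate_cohort(study_params), dictionary_for_params(study_params))


@pytest.fixture()
def tiny_cohort():
    """Hand-built 6-patient cohort with one ELISA and one (partly missing) MRM marker."""
    df = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C", "D", "E", "F"],
            "age": [50.0, 61.0, 57.0, 44.0, 70.0, 66.0],
            "baseline_score": [0.05, 0.40, 0.22, 0.10, 0.65, 0.33],
            "opn": [10.0, 30.0, 25.0, 8.0, 50.0, 28.0],
            "pep1": [1.2, np.nan, 2.0, np.nan, 3.1, np.nan],
            "cac_agatston": [0.0, 150.0, 90.0, 0.0, 400.0, 120.0],
        }
    )
    dd = DataDictionary(
        roles={
            "patient_id": "id",
            "age": "covariate",
            "baseline_score": "score",
            "opn": "marker",
            "pep1": "marker",
            "cac_agatston": "cac",
        },
        assays={"opn": "ELISA", "pep1": "MRM"},
    )
    return CohortTable(df, dd)
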