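import dataclasses

import numpy as np
import pandas as pd
import pytest

from labmort import (MortalityModel, SyntheticParams, build_value_summary,
                     generate_synthetic_cohort)
from labmort.lis_data import Cohort

SMALL_PARAMS = dataclasses.replace(SyntheticParams(), n_patients=400)


def make_cohort(results_rows, patients_rows, contexts_rows=None) -> Cohort:
    """Hand-built cohort from row tuples; contexts default to outpatient/Others."""
    results = pd.DataFrame(results_rows,
                           columns=["patient_id", "test_date", "item_code", "value"])
    results["test_date"] = pd.to_datetime(results["test_date"])
    patients = pd.DataFrame(patients_rows,
                            columns=["patient_id", "sex", "birth_date",
                                     "death_date", "dialysis"])
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    patients["death_date"] = pd.to_datetime(patients["death_date"])
    if contexts_rows is None:
        days = results[["patient_id", "test_date"]].drop_duplicates()
        contexts = days.assign(department="Others", location="outpatient")
    else:
        contexts = pd.DataFrame(contexts_rows,
                                columns=["patient_id", "test_date",
                                         "department", "location"])
        contexts["test_date"] = pd.to_datetime(contexts["test_date"])
    return Cohort(results.reset_index(drop=True), patients, contexts.reset_index(drop=True))


@pytest.fixture(scope="session")
def small_cohort():
    """~1,600-patient-day synthetic cohort shared across tests."""
    return generate_synthetic_cohort(SMALL_PARAMS, seed=11)


@pytest.fixture(scope="session")
def small_summary(small_cohort):
    return build_value_summary(small_cohort.results)


@pytest.fixture(scope="session")
def small_features(small_cohort, small_summary):
    model = MortalityModel.from_cohort(small_cohort, small_summary)
    return model.features


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two patients, five results, one deceased."""
    return make_cohort(
        [("A", "2019-01-01", "glucose", 100.0),
         ("A", "2019-01-01", "sodium", 141.0),
         ("A", "2019-01-05", "glucose", 250.0),
         ("B", "2019-02-01", "glucose", 90.0),
         ("B", "2019-02-01", "potassium", 4.1)],
        [("A", "male", "1950-06-15", "2019-01-08", 0),
         ("B", "female", "1980-03-02", pd.NaT, 1)],
    )
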