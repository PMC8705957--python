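import numpy as np
import pandas as pd
import pytest

import hepiron
from hepiron.cohort import VariablePanel


@pytest.fixture(scope="session")
def study_cohort():
    """Default calibrated synthetic cohort (206 men / 147 women), seed 1."""
    return hepiron.generate_cohort(hepiron.default_study_config(), seed=1)


@pytest.fixture(scope="session")
def study_strata(study_cohort):
    male, female = study_cohort.stratify_by_sex()
    return {"male": male, "female": female}


@pytest.fixture(scope="session")
def default_panel(study_cohort):
    return VariablePanel.default(study_cohort.catalog)


def make_cohort(df: pd.DataFrame, catalog=None) -> "hepiron.Cohort":
    return hepiron.Cohort(df, catalog)


@pytest.fixture
def tiny_cohort():
    """Hand-built 6-row cohort with simple continuous covariates."""
    df = pd.DataFrame({
        "id": [f"P{i}" for i in range(6)],
        "sex": ["male", "male", "male", "female", "female", "female"],
        "hic": [40.0, 42.0, 44.0, 38.0, 39.0, 41.0],
        "hff": [3.0, 6.0, 9.0, 2.0, 4.0, 8.0],
        "age": [50.0, 55.0, 60.0, 48.0, 52.0, 63.0],
    })
    return hepiron.Cohort(df, catalog={
        "age": hepiron.VariableDef("age", units="years"),
        "hff": hepiron.VariableDef("hff", log_transform=True, units="%"),
    })
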