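import numpy as np
import pandas as pd
import pytest

from cohortforge import (
    EhrDataset,
    FixtureSpec,
    PopulationParams,
    builtin_templates,
    generate_fixture,
    generate_population,
)


@pytest.fixture(scope="session")
def library():
    return builtin_templates()


@pytest.fixture(scope="session")
def small_fixture_ds():
    """Small deterministic fixture exercising every cohort-flow category."""
    spec = FixtureSpec(
        eligible_untreated=6, eligible_treated=4, no_followup=3,
        prior_malignancy=3, prior_fracture=2, prior_aom=2,
        under_50=2, paget_history=1, outside_window=2, seed=11,
    )
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def medium_population_ds():
    """Shared stochastic dataset for report/engine tests."""
    return generate_population(PopulationParams(
        n_patients=400, yearly_incidence=0.25, seed=5,
    ))


def make_patient(pid, birth, sex="female", bmi=24.0, marital="married",
                 income="normal", occupation="retired", death=None):
    return {
        "patient_id": pid, "birth_date": pd.Timestamp(birth), "sex": sex,
        "bmi": bmi, "marital_status": marital, "income_level": income,
        "occupation": occupation,
        "death_date": pd.Timestamp(death) if death else pd.NaT,
    }


def make_event(pid, day, dimension="diagnosis", code="820.8",
               setting="outpatient", duration=None):
    return {
        "patient_id": pid, "event_date": pd.Timestamp(day),
        "dimension": dimension, "code": code, "setting": setting,
        "duration_days": duration if duration is not None else pd.NA,
    }


def make_encounter(pid, day, setting="outpatient"):
    return {"patient_id": pid, "encounter_date": pd.Timestamp(day), "setting": setting}
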