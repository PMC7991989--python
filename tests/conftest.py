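"""Shared fixtures: small synthetic cohorts and hand-built label tables."""

import numpy as np
import pandas as pd
import pytest

from gdm_escalation.config import SimConfig
from gdm_escalation.schema import MEAL_TAGS, PATIENT_COLUMNS, RISK_FLAGS
from gdm_escalation.synthetic import generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(n_patients=60, monitoring_days=28, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def medium_cohort():
    return generate_cohort(SimConfig(n_patients=200, seed=1))


def make_patient(pid="P1", age=30.0, bmi=28.0, diabetes_type="GDM",
                 delivery=None, **flags):
    """One patients-table row with sane defaults."""
    row = {
        "patient_id": pid, "age": age, "bmi": bmi, "ethnicity_risk": 0,
        **{f: 0 for f in RISK_FLAGS},
        "diabetes_type": diabetes_type,
        "delivery_date": delivery or pd.Timestamp("2019-03-01"),
    }
    row.update(flags)
    return pd.DataFrame([row])[list(PATIENT_COLUMNS)]


def make_readings(pid="P1", start="2019-01-01", n_days=7, per_day=6,
                  value=5.0):
    """Regular readings: ``per_day`` tags per day at fixed clock times."""
    rows = []
    start = pd.Timestamp(start)
    for d in range(n_days):
        for k in range(per_day):
            rows.append({
                "patient_id": pid,
                "timestamp": start + pd.Timedelta(days=d, hours=7 + 2 * k),
                "meal_tag": MEAL_TAGS[k % len(MEAL_TAGS)],
                "bg_mmol": value,
                "entry_method": "manual",
            })
    return pd.DataFrame(rows)


def empty_medications():
    return pd.DataFrame(columns=["patient_id", "date", "medication"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
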