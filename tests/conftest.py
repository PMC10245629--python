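import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pmxcea
from pmxcea.lifetable import make_fixture_life_table

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    """Generator config calibrated to the published unmatched margins."""
    return pmxcea.default_config_from_table1(n_patients=20_000, seed=1)


@pytest.fixture(scope="session")
def big_cohort(default_config):
    """One 20,000-admission synthetic cohort, shared across the session."""
    return pmxcea.generate_cohort(default_config)


@pytest.fixture(scope="session")
def labeled_cohort(big_cohort):
    eligible, report = pmxcea.select_cohort(big_cohort)
    labeled = pmxcea.assign_groups(eligible)
    return labeled, report


@pytest.fixture(scope="session")
def life_table():
    return make_fixture_life_table()


@pytest.fixture(scope="session")
def fitted(big_cohort, life_table):
    """Full pipeline fit on the shared 20k cohort."""
    model = pmxcea.CostEffectivenessModel(big_cohort, life_table)
    return model.fit(seed=1)


@pytest.fixture()
def small_cohort():
    return pmxcea.generate_cohort(
        pmxcea.default_config_from_table1(n_patients=1500, seed=7)
    )


def make_patient(**overrides) -> dict:
    """A single eligible control patient row; override fields as needed."""
    row = {
        "patient_id": "P000000",
        "age": 70,
        "sex": "male",
        "emergency_admission": True,
        "university_hospital": False,
        "er_icu_admission": True,
        "cci": 2,
        "sofa_baseline": 9,
        "crrt": False,
        "hd": False,
        "mechanical_ventilation": False,
        "surgery": False,
        "gamma_globulin": False,
        "at3": False,
        "rtm": False,
        "steroid": False,
        "rbc_transfusion": False,
        "platelet_transfusion": False,
        "max_noradrenaline": 5.0,
        "abdominal_infection": False,
        "pmx_day": np.nan,
        "death_day": np.nan,
        "los_days": 20,
        "transfer_without_recovery_day": np.nan,
        "ventilator_days": frozenset(),
        "vasopressor_days": frozenset(),
        "crrt_days": frozenset(),
    }
    for cat in pmxcea.economics.COST_CATEGORIES:
        row[f"cost_jpy_{cat}"] = 0.0
    row.update(overrides)
    return row


def patients_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([make_patient(**r) for r in rows])


@pytest.fixture()
def toy_frame():
    return patients_frame
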