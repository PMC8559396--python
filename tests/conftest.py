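import dataclasses

import numpy as np
import pytest

from hale import Thresholds, default_dictionary, default_spec, generate_cohort
from hale.variables import DISEASES, PERF_ITEMS


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_cohort():
    """400-record default-style cohort with unit weights and no missingness."""
    from hale.synthetic_cohort import WeightModel

    spec = dataclasses.replace(default_spec(), n=400, seed=7, missingness={},
                               weights=WeightModel("unit"))
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions (n=1797, published margins and weights)."""
    spec = dataclasses.replace(default_spec(), seed=2010)
    return generate_cohort(spec)


def base_healthy_values() -> dict:
    """A record meeting every healthy criterion in every domain."""
    values = {
        "sex": "man", "age_group": "65-74", "area": "urban",
        "ethnicity": "mestizo", "education": "primary",
        "perceived_health": "good", "life_satisfaction": 1, "income_poverty": 0,
        "med_count": 1, "urinary_incontinence": 0, "fecal_incontinence": 0,
        "falls_count": 0,
        "systolic_bp": 120.0, "diastolic_bp": 70.0, "fasting_glucose": 90.0,
        "bmi": 24.0, "lipids_abnormal": 0, "alcohol_days_week": 0,
        "tobacco_use": 0, "physically_active": 1,
        "katz_disability": 0, "minimental": 19, "dementia_dx": 0,
        "abuse_physical": 0, "abuse_sexual": 0, "abuse_psychological": 0,
        "yesavage": 10, "negligence": 0, "economic_violence": 0, "gijon": 6,
        "social_security": 1, "pension": 0, "health_access": 1,
        "institutional_support": 1, "recreation": 1, "volunteer_monthly": 1,
        "support_received": 1, "support_provided": 0,
    }
    for disease in DISEASES:
        values[f"dx_{disease}"] = 0
        values[f"dx_{disease}_controlled"] = 0
    for item in PERF_ITEMS:
        values[item] = 1
    return values


@pytest.fixture()
def healthy_values():
    return base_healthy_values()


def rng(seed=0):
    return np.random.default_rng(seed)
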