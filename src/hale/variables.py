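"""The default variable dictionary for SABE-style older-adult cohorts.

Names the raw survey indicators the healthy-ageing model consumes:
demographics and socio-economic outcomes, chronic-disease diagnoses with
controlled/non-limiting flags, geriatric-syndrome items, cardiovascular
risk measurements, physical-performance items with the Katz ADL disability
flag, the modified Mini-Mental total, the Yesavage depression score, the
Gijón socio-familial score, and the social/political environment and
interaction flags.
"""

from __future__ import annotations

from .survey_io import VariableDef, VariableDictionary

#: chronic-disease slots of the physiological/metabolic domain
DISEASES = (
    "hypertension",
    "diabetes",
    "cancer",
    "lung_disease",
    "cardiovascular_disease",
    "cerebrovascular_disease",
    "arthritis",
    "osteoporosis",
    "other_chronic",
)

#: self-reported balance / chair-rise performance items (7)
N_PERF_ITEMS = 7
PERF_ITEMS = tuple(f"perf_item_{i}" for i in range(1, N_PERF_ITEMS + 1))

SEX_CODES = ("man", "woman")
AGE_CODES = ("65-74", "75-84", "85+")
AREA_CODES = ("urban", "rural")
ETHNICITY_CODES = ("mestizo", "white", "indigenous", "mulatto", "afro_ecuadorian", "other")
EDUCATION_CODES = ("none", "literacy_center", "kindergarten", "primary",
                   "high_school", "college", "postgraduate")
HEALTH_CODES = ("bad", "regular", "good", "very_good", "excellent")

#: modified Mini-Mental total range in this survey's scoring
MINIMENTAL_MAX = 19
YESAVAGE_MAX = 15
GIJON_MAX = 25


def default_dictionary() -> VariableDictionary:
    """Build the shipped variable dictionary (demographics + all domain inputs)."""
    entries: list[VariableDef] = [
        VariableDef("sex", "categorical", SEX_CODES),
        VariableDef("age_group", "categorical", AGE_CODES),
        VariableDef("area", "categorical", AREA_CODES),
        VariableDef("ethnicity", "categorical", ETHNICITY_CODES),
        VariableDef("education", "categorical", EDUCATION_CODES),
        VariableDef("perceived_health", "categorical", HEALTH_CODES),
        VariableDef("life_satisfaction", "binary"),
        VariableDef("income_poverty", "binary"),
    ]
    for disease in DISEASES:
        entries.append(VariableDef(f"dx_{disease}", "binary"))
        entries.append(VariableDef(f"dx_{disease}_controlled", "binary"))
    entries += [
        VariableDef("med_count", "count", unit="medications"),
        VariableDef("urinary_incontinence", "binary"),
        VariableDef("fecal_incontinence", "binary"),
        VariableDef("falls_count", "count", unit="falls/year"),
        VariableDef("systolic_bp", "real", unit="mmHg"),
        VariableDef("diastolic_bp", "real", unit="mmHg"),
        VariableDef("fasting_glucose", "real", unit="mg/dL"),
        VariableDef("bmi", "real", unit="kg/m2"),
        VariableDef("lipids_abnormal", "binary"),
        VariableDef("alcohol_days_week", "count", unit="days/week"),
        VariableDef("tobacco_use", "binary"),
        VariableDef("physically_active", "binary"),
    ]
    for item in PERF_ITEMS:
        entries.append(VariableDef(item, "binary"))
    entries += [
        VariableDef("katz_disability", "binary"),
        VariableDef("minimental", "count", unit="points"),
        VariableDef("dementia_dx", "binary"),
        VariableDef("abuse_physical", "binary"),
        VariableDef("abuse_sexual", "binary"),
        VariableDef("abuse_psychological", "binary"),
        VariableDef("yesavage", "count", unit="points"),
        VariableDef("negligence", "binary"),
        VariableDef("economic_violence", "binary"),
        VariableDef("gijon", "count", unit="points"),
        VariableDef("social_security", "binary"),
        VariableDef("pension", "binary"),
        VariableDef("health_access", "binary"),
        VariableDef("institutional_support", "binary"),
        VariableDef("recreation", "binary"),
        VariableDef("volunteer_monthly", "binary"),
        VariableDef("support_received", "binary"),
        VariableDef("support_provided", "binary"),
    ]
    return VariableDictionary(entries)
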