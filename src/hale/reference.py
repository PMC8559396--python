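"""Published weighted contingency counts from the SABE-Ecuador 2010 analysis.

These are the expansion-weighted healthy / less-healthy cell counts of the
published cross-tables (population persons, not respondents). They serve as
worked-example inputs: forming 2x2 tables against each variable's reference
level and taking cross-product odds ratios reproduces the published
bivariate odds-ratio column.

The ethnicity rows are shipped for completeness but excluded from the
worked examples: the published ethnicity odds ratios cannot be reproduced
from these counts (the reference coding used there is not recoverable), and
the bachelor / postgraduate education rows have zero less-healthy cells.
"""

from __future__ import annotations

from .survey_logistic import ORResult, crude_or

__all__ = ["WEIGHTED_COUNTS", "REFERENCE_LEVELS", "WORKED_CONTRASTS",
           "published_bivariate_ors"]

#: variable -> level -> (weighted healthy, weighted less-healthy)
WEIGHTED_COUNTS = {
    "sex": {
        "man": (200_574.0, 129_623.0),
        "woman": (205_012.0, 226_230.0),
    },
    "age_group": {
        "65-74": (239_846.0, 177_899.0),
        "75-84": (117_437.0, 111_549.0),
        "85+": (16_204.0, 35_773.0),
    },
    "area": {
        "urban": (292_002.0, 231_828.0),
        "rural": (113_750.0, 125_850.0),
    },
    "ethnicity": {
        "mestizo": (280_883.0, 220_681.0),
        "white": (53_999.0, 50_923.0),
        "indigenous": (23_955.0, 44_451.0),
        "afro_ecuadorian": (15_452.0, 8_436.0),
        "mulatto": (14_900.0, 11_408.0),
        "other": (4_367.0, 6_977.0),
    },
    "education": {
        "none": (4_903.0, 7_036.0),
        "literacy_center": (4_522.0, 12_862.0),
        "kindergarten": (1_212.0, 1_533.0),
        "primary": (240_836.0, 198_513.0),
        "high_school": (58_032.0, 18_293.0),
        "bachelor": (1_717.0, 0.0),
        "college": (18_143.0, 2_102.0),
        "postgraduate": (2_254.0, 0.0),
    },
    "perceived_health": {
        "excellent": (7_180.0, 670.0),
        "very_good": (14_484.0, 4_440.0),
        "good": (117_367.0, 41_697.0),
        "regular": (224_147.0, 196_861.0),
        "bad": (42_574.0, 113_200.0),
    },
    "life_satisfaction": {
        "yes": (373_827.0, 263_883.0),
        "no": (30_986.0, 92_084.0),
    },
    "income_poverty": {
        "no": (272_076.0, 169_120.0),
        "yes": (133_676.0, 188_558.0),
    },
}

REFERENCE_LEVELS = {
    "sex": "man",
    "age_group": "65-74",
    "area": "urban",
    "ethnicity": "mestizo",
    "education": "primary",
    "perceived_health": "bad",
    "life_satisfaction": "yes",
    "income_poverty": "no",
}

#: the (variable, level) contrasts of the published bivariate worked examples
WORKED_CONTRASTS = (
    ("sex", "woman"),
    ("age_group", "75-84"),
    ("age_group", "85+"),
    ("area", "rural"),
    ("education", "high_school"),
    ("perceived_health", "excellent"),
    ("perceived_health", "very_good"),
    ("perceived_health", "good"),
    ("perceived_health", "regular"),
    ("life_satisfaction", "no"),
    ("income_poverty", "yes"),
)


def published_bivariate_ors() -> list[ORResult]:
    """Recompute the worked-example crude ORs from the published weighted cells."""
    results = []
    for variable, level in WORKED_CONTRASTS:
        reference = REFERENCE_LEVELS[variable]
        a, b = WEIGHTED_COUNTS[variable][level]
        c, d = WEIGHTED_COUNTS[variable][reference]
        results.append(crude_or(a, b, c, d, variable=variable, level=level,
                                reference=reference))
    return results
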