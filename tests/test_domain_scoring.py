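"""Rule-engine tests: worked examples, exhaustive enumeration oracles per
domain, monotonicity, missing-input handling and threshold configuration."""

import itertools
import math

import pytest

from hale import SurveyRecord, Thresholds, score_person
from hale.domain_scoring import (
    CLASSIFIERS,
    DOMAIN_IDS,
    DOMAIN_MODEL,
    HEALTHY,
    LESS_HEALTHY,
)
from hale.variables import DISEASES, PERF_ITEMS

from conftest import base_healthy_values

# --- deterministic raw-value builders: criterion pattern -> record ---------

def _apply_pattern(domain, values, pattern):
    if domain == "physiological":
        for met, disease in zip(pattern, DISEASES):
            values[f"dx_{disease}"] = 0 if met else 1
            values[f"dx_{disease}_controlled"] = 0
    elif domain == "geriatric_syndromes":
        values["med_count"] = 2 if pattern[0] else 6
        values["urinary_incontinence"] = 0 if pattern[1] else 1
        values["fecal_incontinence"] = 0 if pattern[2] else 1
        values["falls_count"] = 0 if pattern[3] else 3
    elif domain == "risk_factors":
        values["systolic_bp"], values["diastolic_bp"] = \
            (120.0, 70.0) if pattern[0] else (160.0, 95.0)
        values["fasting_glucose"] = 90.0 if pattern[1] else 150.0
        values["bmi"] = 24.0 if pattern[2] else 33.0
        values["lipids_abnormal"] = 0 if pattern[3] else 1
        values["alcohol_days_week"] = 0 if pattern[4] else 3
        values["tobacco_use"] = 0 if pattern[5] else 1
        values["physically_active"] = 1 if pattern[6] else 0
    elif domain == "physical":
        for met, item in zip(pattern[:7], PERF_ITEMS):
            values[item] = 1 if met else 0
        values["katz_disability"] = 0 if pattern[7] else 1
    elif domain == "cognitive":
        values["dementia_dx"] = 0 if pattern[0] else 1
        values["minimental"] = 15 if pattern[1] else 10
    elif domain == "psychological":
        values["abuse_physical"] = 0 if pattern[0] else 1
        values["abuse_sexual"] = 0 if pattern[1] else 1
        values["abuse_psychological"] = 0 if pattern[2] else 1
        values["yesavage"] = 10 if pattern[3] else 2  # printed rule: <=4 depressed
    elif domain == "social_welfare":
        values["negligence"] = 0 if pattern[0] else 1
        values["economic_violence"] = 0 if pattern[1] else 1
        values["gijon"] = 6 if pattern[2] else 12
    elif domain == "political_env":
        values["social_security"] = 1 if pattern[0] else 0
        values["pension"] = 0
        values["health_access"] = 1 if pattern[1] else 0
        values["institutional_support"] = 1 if pattern[2] else 0
    elif domain == "participation":
        values["recreation"] = 1 if pattern[0] else 0
        values["volunteer_monthly"] = 1 if pattern[1] else 0
    elif domain == "support":
        values["support_received"] = 1 if pattern[0] else 0
        values["support_provided"] = 0
    return values


def _record_for(domain, pattern):
    return SurveyRecord("t", 1.0, _apply_pattern(domain, base_healthy_values(),
                                                 list(pattern)))


def _oracle(domain, pattern):
    """Independent class/score arithmetic for a criterion pattern."""
    met, total = sum(pattern), len(pattern)
    score = math.floor(10.0 * met / total + 0.5)
    if domain == "physical":
        healthy = sum(pattern[:7]) >= 6 and pattern[7]
    else:
        healthy = met == total
    return score, HEALTHY if healthy else LESS_HEALTHY


N_CRITERIA = {spec.domain_id: spec.n_criteria for spec in DOMAIN_MODEL}


@pytest.mark.parametrize("domain", DOMAIN_IDS)
def test_exhaustive_enumeration_matches_oracle(domain, thresholds):
    """Every criterion combination classifies and scores exactly as the
    independent enumeration oracle says."""
    c = N_CRITERIA[domain]
    for pattern in itertools.product([True, False], repeat=c):
        result = CLASSIFIERS[domain](_record_for(domain, pattern), thresholds)
        score, cls = _oracle(domain, pattern)
        assert result.evaluable
        assert result.applicable == c
        assert result.met == sum(pattern)
        assert result.score == score, (domain, pattern)
        assert result.cls == cls, (domain, pattern)


@pytest.mark.parametrize("domain", DOMAIN_IDS)
def test_meeting_one_more_criterion_never_hurts(domain, thresholds):
    """Monotonicity: flipping a single criterion from unmet to met never
    lowers the score and never flips the class from healthy to less healthy."""
    c = N_CRITERIA[domain]
    for pattern in itertools.product([True, False], repeat=c):
        base = CLASSIFIERS[domain](_record_for(domain, pattern), thresholds)
        for i, met in enumerate(pattern):
            if met:
                continue
            better = list(pattern)
            better[i] = True
            upgraded = CLASSIFIERS[domain](_record_for(domain, better), thresholds)
            assert upgraded.score >= base.score
            assert not (base.cls == HEALTHY and upgraded.cls == LESS_HEALTHY)


@pytest.mark.parametrize(
    "domain,mutate,expect_cls,expect_score",
    [
        # chronic diseases: none -> healthy 10; uncontrolled hypertension -> less;
        # controlled diabetes alone -> healthy
        ("physiological", {}, HEALTHY, 10),
        ("physiological", {"dx_hypertension": 1, "dx_hypertension_controlled": 0},
         LESS_HEALTHY, 9),
        ("physiological", {"dx_diabetes": 1, "dx_diabetes_controlled": 1}, HEALTHY, 10),
        # geriatric syndromes: polypharmacy alone -> 3 of 4 met
        ("geriatric_syndromes", {}, HEALTHY, 10),
        ("geriatric_syndromes", {"med_count": 6}, LESS_HEALTHY, 8),
        ("geriatric_syndromes", {"fecal_incontinence": 1}, LESS_HEALTHY, 8),
        # risk factors: BMI 31 the only violation -> round(10*6/7)=9;
        # blood pressure exactly 150/90 is NOT a violation (rule is strict >)
        ("risk_factors", {}, HEALTHY, 10),
        ("risk_factors", {"bmi": 31.0}, LESS_HEALTHY, 9),
        ("risk_factors", {"systolic_bp": 150.0, "diastolic_bp": 90.0}, HEALTHY, 10),
        # physical capacity: 6 of 7 still healthy, 5 of 7 not
        ("physical", {"perf_item_1": 0}, HEALTHY, 9),
        ("physical", {"perf_item_1": 0, "perf_item_2": 0}, LESS_HEALTHY, 8),
        ("physical", {"katz_disability": 1}, LESS_HEALTHY, 9),
        # cognition: 14 healthy, 12 deficit, 13 in the gap -> less healthy
        ("cognitive", {"minimental": 14}, HEALTHY, 10),
        ("cognitive", {"minimental": 12}, LESS_HEALTHY, 5),
        ("cognitive", {"minimental": 13}, LESS_HEALTHY, 5),
        # psychological: printed depression rule (<=4 depressed)
        ("psychological", {"yesavage": 10}, HEALTHY, 10),
        ("psychological", {"abuse_psychological": 1}, LESS_HEALTHY, 8),
        ("psychological", {"abuse_physical": 1, "abuse_sexual": 1,
                           "abuse_psychological": 1, "yesavage": 2}, LESS_HEALTHY, 0),
        # social welfare: Gijon 9 ok, 11 altered, 10 in the gap -> less healthy
        ("social_welfare", {"gijon": 9}, HEALTHY, 10),
        ("social_welfare", {"gijon": 11}, LESS_HEALTHY, 7),
        ("social_welfare", {"gijon": 10}, LESS_HEALTHY, 7),
        # political environment: pension alone satisfies the coverage disjunction
        ("political_env", {"social_security": 0, "pension": 1}, HEALTHY, 10),
        ("political_env", {"social_security": 0, "pension": 0}, LESS_HEALTHY, 7),
        ("political_env", {"social_security": 0, "pension": 0, "health_access": 0,
                           "institutional_support": 0}, LESS_HEALTHY, 0),
        # participation and support
        ("participation", {}, HEALTHY, 10),
        ("participation", {"volunteer_monthly": 0}, LESS_HEALTHY, 5),
        ("participation", {"recreation": 0, "volunteer_monthly": 0}, LESS_HEALTHY, 0),
        ("support", {"support_received": 0, "support_provided": 1}, HEALTHY, 10),
        ("support", {"support_received": 1, "support_provided": 1}, HEALTHY, 10),
        ("support", {"support_received": 0, "support_provided": 0}, LESS_HEALTHY, 0),
    ],
)
def test_published_rule_examples(domain, mutate, expect_cls, expect_score, thresholds):
    values = base_healthy_values()
    values.update(mutate)
    result = CLASSIFIERS[domain](SurveyRecord("t", 1.0, values), thresholds)
    assert result.cls == expect_cls
    assert result.score == expect_score


def test_all_inputs_missing_makes_domain_non_evaluable(thresholds):
    values = base_healthy_values()
    for key in ("med_count", "urinary_incontinence", "fecal_incontinence",
                "falls_count"):
        values[key] = None
    result = CLASSIFIERS["geriatric_syndromes"](SurveyRecord("t", 1.0, values),
                                                thresholds)
    assert not result.evaluable


def test_missing_criterion_dropped_from_applicable(thresholds):
    values = base_healthy_values()
    values["med_count"] = None
    result = CLASSIFIERS["geriatric_syndromes"](SurveyRecord("t", 1.0, values),
                                                thresholds)
    assert result.evaluable
    assert result.applicable == 3
    assert result.score == 10


def test_minimental_out_of_range_raises(thresholds):
    values = base_healthy_values()
    values["minimental"] = 25
    with pytest.raises(ValueError, match="Mini-Mental"):
        CLASSIFIERS["cognitive"](SurveyRecord("t", 1.0, values), thresholds)


def test_yesavage_direction_configurable(healthy_values):
    """Under the conventional GDS direction a high score flags depression."""
    conventional = Thresholds(yesavage_direction="ge", yesavage_cut=5)
    values = dict(healthy_values)
    values["yesavage"] = 10
    result = CLASSIFIERS["psychological"](SurveyRecord("t", 1.0, values), conventional)
    assert result.cls == LESS_HEALTHY


def test_gap_values_configurable(healthy_values):
    lenient = Thresholds(minimental_gap_to_healthy=True, gijon_gap_to_healthy=True)
    values = dict(healthy_values)
    values["minimental"], values["gijon"] = 13, 10
    assert CLASSIFIERS["cognitive"](SurveyRecord("t", 1.0, values), lenient).cls == HEALTHY
    assert CLASSIFIERS["social_welfare"](SurveyRecord("t", 1.0, values), lenient).cls == HEALTHY


def test_score_person_composes_the_ten_classifiers(small_cohort, thresholds):
    records, _ = small_cohort
    for record in records[:50]:
        profile = score_person(record, thresholds)
        assert [s.domain_id for s in profile.scores] == list(DOMAIN_IDS)
        for score, domain in zip(profile.scores, DOMAIN_IDS):
            solo = CLASSIFIERS[domain](record, thresholds)
            assert (score.met, score.applicable, score.score, score.cls) == \
                (solo.met, solo.applicable, solo.score, solo.cls)
        assert not profile.excluded


def test_excluded_when_too_many_domains_non_evaluable(healthy_values):
    values = {k: None for k in healthy_values}
    profile = score_person(SurveyRecord("t", 1.0, values))
    assert profile.excluded
    assert all(not s.evaluable for s in profile.scores)


def test_thresholds_yaml_round_trip_preserves_classifications(tmp_path, small_cohort):
    custom = Thresholds(polypharmacy_cut=4, falls_cut=3, yesavage_direction="ge",
                        yesavage_cut=6, minimental_gap_to_healthy=True)
    path = tmp_path / "thr.yaml"
    custom.to_yaml(path)
    reloaded = Thresholds.from_yaml(path)
    assert reloaded == custom
    records, _ = small_cohort
    for record in records[:100]:
        a = score_person(record, custom)
        b = score_person(record, reloaded)
        assert a.score_vector() == b.score_vector()
        assert a.class_vector() == b.class_vector()
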