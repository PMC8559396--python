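"""Rule engine for the ten healthy-ageing domains.

Each respondent is evaluated against per-domain criterion lists (chronic
diseases absent or controlled, geriatric syndromes absent, cardiovascular
risk factors absent, physical performance and ADL independence, cognition,
psychological well-being, social welfare, political environment,
community participation, family support). Every domain yields

* a binary class — ``healthy`` / ``less_healthy`` — from the domain's rule,
* an integer intra-domain score 0–10, ``round(10 * met / applicable)``,
  10 being the best attainable health status in that domain.

Criteria whose inputs are missing are dropped from the applicable set
rather than imputed; a domain with no applicable criterion is flagged
non-evaluable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .survey_io import SurveyRecord
from .variables import (
    DISEASES,
    GIJON_MAX,
    MINIMENTAL_MAX,
    N_PERF_ITEMS,
    PERF_ITEMS,
    YESAVAGE_MAX,
)

__all__ = [
    "Thresholds",
    "DomainSpec",
    "DomainScore",
    "PersonProfile",
    "DOMAIN_IDS",
    "DOMAIN_MODEL",
    "HEALTHY",
    "LESS_HEALTHY",
    "score_person",
    "score_cohort",
    "profiles_to_frame",
]

HEALTHY = "healthy"
LESS_HEALTHY = "less_healthy"

#: canonical domain order (radar axis order)
DOMAIN_IDS = (
    "physiological",
    "geriatric_syndromes",
    "risk_factors",
    "physical",
    "cognitive",
    "psychological",
    "social_welfare",
    "political_env",
    "participation",
    "support",
)


@dataclass
class Thresholds:
    """Instrument cut-offs and operational definitions, all configurable.

    Defaults encode the model as published for the SABE 2010 survey:
    modified Mini-Mental healthy at >= 14 with deficit below 13 (the
    unassigned 13 goes to less_healthy unless ``minimental_gap_to_healthy``),
    depression flagged at Yesavage <= 4 exactly as printed (note this is the
    reverse of standard GDS scoring — set ``yesavage_direction='ge'`` for the
    conventional rule), Gijón good situation at <= 9 (the unassigned 10 goes
    to less_healthy unless ``gijon_gap_to_healthy``), blood pressure healthy
    unless strictly above 150/90, fasting glucose healthy below 126 mg/dL,
    obesity at BMI >= 30 kg/m2, alcohol at most 1 day/week, polypharmacy at
    >= 5 concurrent medications (standard operational definition), falls
    syndrome at >= 2 falls in the past year, and 6 of the 7 performance
    items required for physical capacity.
    """

    minimental_healthy_cut: int = 14
    minimental_deficit_cut: int = 13
    minimental_gap_to_healthy: bool = False
    yesavage_direction: str = "le"  # 'le': depression when score <= cut (as printed)
    yesavage_cut: int = 4
    gijon_good_cut: int = 9
    gijon_gap_to_healthy: bool = False
    systolic_cut: float = 150.0  # unhealthy only when strictly above
    diastolic_cut: float = 90.0
    glucose_cut: float = 126.0  # unhealthy when >= cut
    bmi_cut: float = 30.0  # unhealthy when >= cut
    alcohol_days_cut: int = 1  # unhealthy when > cut days/week
    polypharmacy_cut: int = 5  # unhealthy when med count >= cut
    falls_cut: int = 2  # unhealthy when falls in past year >= cut
    perf_required: int = 6  # of the 7 performance items
    institutional_support_required: bool = True
    max_non_evaluable: int = 3  # domains; beyond this the record is excluded

    def __post_init__(self) -> None:
        if self.yesavage_direction not in ("le", "ge"):
            raise ValueError("yesavage_direction must be 'le' or 'ge'")
        for name in ("minimental_healthy_cut", "gijon_good_cut", "polypharmacy_cut",
                     "falls_cut", "perf_required", "systolic_cut", "diastolic_cut",
                     "glucose_cut", "bmi_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.minimental_deficit_cut > self.minimental_healthy_cut:
            raise ValueError("minimental deficit cut must not exceed healthy cut")

    @property
    def minimental_effective_cut(self) -> int:
        return self.minimental_deficit_cut if self.minimental_gap_to_healthy \
            else self.minimental_healthy_cut

    @property
    def gijon_effective_cut(self) -> int:
        # altered situation starts strictly above 10; the gap value 10 is
        # assigned by configuration
        return self.gijon_good_cut + 1 if self.gijon_gap_to_healthy else self.gijon_good_cut

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "Thresholds":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        return cls(**payload)


@dataclass(frozen=True)
class DomainSpec:
    """Structural description of one domain within the three-component model."""

    domain_id: str
    component: str  # intrinsic | environment | interaction
    n_criteria: int
    rule: str  # all-criteria | threshold-count | any-criterion


#: the ten domains: six intrinsic-capacity, two environment, two interaction
DOMAIN_MODEL = (
    DomainSpec("physiological", "intrinsic", len(DISEASES), "all-criteria"),
    DomainSpec("geriatric_syndromes", "intrinsic", 4, "all-criteria"),
    DomainSpec("risk_factors", "intrinsic", 7, "all-criteria"),
    DomainSpec("physical", "intrinsic", N_PERF_ITEMS + 1, "threshold-count"),
    DomainSpec("cognitive", "intrinsic", 2, "all-criteria"),
    DomainSpec("psychological", "intrinsic", 4, "all-criteria"),
    DomainSpec("social_welfare", "environment", 3, "all-criteria"),
    DomainSpec("political_env", "environment", 3, "all-criteria"),
    DomainSpec("participation", "interaction", 2, "all-criteria"),
    DomainSpec("support", "interaction", 1, "any-criterion"),
)


@dataclass
class DomainScore:
    domain_id: str
    met: int
    applicable: int
    score: int
    cls: str
    evaluable: bool
    criteria: dict = field(default_factory=dict)  # name -> True/False/None


@dataclass
class PersonProfile:
    """Ordered vector of the ten domain scores for one respondent."""

    record_id: str
    scores: list  # list[DomainScore] in DOMAIN_IDS order
    excluded: bool = False

    def score_vector(self):
        return [s.score if s.evaluable else None for s in self.scores]

    def class_vector(self):
        return [s.cls if s.evaluable else None for s in self.scores]

    @property
    def complete(self) -> bool:
        return all(s.evaluable for s in self.scores)


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def _finish(domain_id: str, criteria: list[tuple[str, bool | None]],
            healthy: bool | None) -> DomainScore:
    """Assemble a DomainScore from (criterion, met-or-None) pairs.

    ``healthy=None`` means "all applicable criteria must be met".
    """
    applicable = sum(1 for _, m in criteria if m is not None)
    met = sum(1 for _, m in criteria if m is True)
    if applicable == 0:
        return DomainScore(domain_id, 0, 0, 0, LESS_HEALTHY, False,
                           dict(criteria))
    if healthy is None:
        healthy = met == applicable
    score = _round_half_up(10.0 * met / applicable)
    return DomainScore(domain_id, met, applicable, score,
                       HEALTHY if healthy else LESS_HEALTHY, True, dict(criteria))


def _flag_absent(record: SurveyRecord, name: str) -> bool | None:
    """Criterion 'adverse flag absent': met when the flag is 0."""
    value = record.get(name)
    return None if value is None else value == 0


def classify_physiological(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """Chronic diseases absent, or present but controlled / non-limiting.

    One criterion per disease slot; a criterion is met when the diagnosis is
    absent or when it is flagged as under treatment and not limiting
    functional status.
    """
    criteria: list[tuple[str, bool | None]] = []
    for disease in DISEASES:
        dx = record.get(f"dx_{disease}")
        if dx is None:
            criteria.append((disease, None))
        elif dx == 0:
            criteria.append((disease, True))
        else:
            controlled = record.get(f"dx_{disease}_controlled")
            criteria.append((disease, None if controlled is None else controlled == 1))
    return _finish("physiological", criteria, None)


def classify_geriatric_syndromes(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """No polypharmacy, no urinary or fecal incontinence, no falls syndrome."""
    meds = record.get("med_count")
    falls = record.get("falls_count")
    criteria = [
        ("no_polypharmacy", None if meds is None else meds < thresholds.polypharmacy_cut),
        ("no_urinary_incontinence", _flag_absent(record, "urinary_incontinence")),
        ("no_fecal_incontinence", _flag_absent(record, "fecal_incontinence")),
        ("no_falls_syndrome", None if falls is None else falls < thresholds.falls_cut),
    ]
    return _finish("geriatric_syndromes", criteria, None)


def classify_risk_factors(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """Absence of cardiovascular risk factors and risk behaviours.

    Blood pressure counts as unhealthy only when strictly above 150/90;
    fasting glucose at >= 126 mg/dL; obesity at BMI >= 30; abnormal ATP-III
    lipids; alcohol more than 1 day/week; current-or-past tobacco use; and
    physical inactivity.
    """
    sys_bp, dia_bp = record.get("systolic_bp"), record.get("diastolic_bp")
    if sys_bp is None or dia_bp is None:
        bp_ok = None
    else:
        bp_ok = not (sys_bp > thresholds.systolic_cut or dia_bp > thresholds.diastolic_cut)
    glucose = record.get("fasting_glucose")
    bmi = record.get("bmi")
    alcohol = record.get("alcohol_days_week")
    active = record.get("physically_active")
    criteria = [
        ("blood_pressure_ok", bp_ok),
        ("glucose_ok", None if glucose is None else glucose < thresholds.glucose_cut),
        ("not_obese", None if bmi is None else bmi < thresholds.bmi_cut),
        ("lipids_ok", _flag_absent(record, "lipids_abnormal")),
        ("alcohol_ok", None if alcohol is None else alcohol <= thresholds.alcohol_days_cut),
        ("no_tobacco", _flag_absent(record, "tobacco_use")),
        ("physically_active", None if active is None else active == 1),
    ]
    return _finish("risk_factors", criteria, None)


def classify_physical(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """Performance items met (6 of 7 required) and no Katz ADL disability.

    The score is computed over 8 criteria (7 items + ADL independence). When
    some items are missing the 6-of-7 requirement is prorated to the
    applicable items, ``ceil(required/7 * applicable)``.
    """
    import math

    criteria: list[tuple[str, bool | None]] = []
    for item in PERF_ITEMS:
        value = record.get(item)
        criteria.append((item, None if value is None else value == 1))
    katz_ok = _flag_absent(record, "katz_disability")
    criteria.append(("no_adl_disability", katz_ok))

    item_states = [m for name, m in criteria[:N_PERF_ITEMS] if m is not None]
    if not item_states and katz_ok is None:
        return _finish("physical", criteria, None)
    if item_states:
        required = math.ceil(thresholds.perf_required / N_PERF_ITEMS * len(item_states))
        items_ok = sum(item_states) >= required
    else:
        items_ok = True  # only the ADL criterion is applicable
    healthy = items_ok and (katz_ok is not False)
    return _finish("physical", criteria, healthy)


def classify_cognitive(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """No dementia diagnosis and modified Mini-Mental above the deficit cut."""
    mm = record.get("minimental")
    if mm is not None and not (0 <= mm <= MINIMENTAL_MAX):
        raise ValueError(
            f"record {record.record_id}: Mini-Mental score {mm} outside 0..{MINIMENTAL_MAX}"
        )
    criteria = [
        ("no_dementia", _flag_absent(record, "dementia_dx")),
        ("minimental_ok", None if mm is None else mm >= thresholds.minimental_effective_cut),
    ]
    return _finish("cognitive", criteria, None)


def classify_psychological(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """No physical, sexual or psychological abuse, and no depression.

    The depression rule follows the survey's printed direction by default
    (Yesavage <= 4 flags depression); ``yesavage_direction='ge'`` gives the
    conventional GDS direction instead.
    """
    ys = record.get("yesavage")
    if ys is not None and not (0 <= ys <= YESAVAGE_MAX):
        raise ValueError(f"record {record.record_id}: Yesavage score {ys} outside 0..{YESAVAGE_MAX}")
    if ys is None:
        depressed = None
    elif thresholds.yesavage_direction == "le":
        depressed = ys <= thresholds.yesavage_cut
    else:
        depressed = ys >= thresholds.yesavage_cut
    criteria = [
        ("no_physical_abuse", _flag_absent(record, "abuse_physical")),
        ("no_sexual_abuse", _flag_absent(record, "abuse_sexual")),
        ("no_psychological_abuse", _flag_absent(record, "abuse_psychological")),
        ("no_depression", None if depressed is None else not depressed),
    ]
    return _finish("psychological", criteria, None)


def classify_social_welfare(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """No negligence, no economic violence, good social situation on Gijón."""
    gijon = record.get("gijon")
    if gijon is not None and not (0 <= gijon <= GIJON_MAX):
        raise ValueError(f"record {record.record_id}: Gijón score {gijon} outside 0..{GIJON_MAX}")
    criteria = [
        ("no_negligence", _flag_absent(record, "negligence")),
        ("no_economic_violence", _flag_absent(record, "economic_violence")),
        ("gijon_ok", None if gijon is None else gijon <= thresholds.gijon_effective_cut),
    ]
    return _finish("social_welfare", criteria, None)


def classify_political_env(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """Social security or a non-contributory pension, health-service access,
    and institutional support (the last configurable as a conjunct)."""
    ss, pension = record.get("social_security"), record.get("pension")
    if ss is None and pension is None:
        coverage = None
    else:
        coverage = (ss == 1) or (pension == 1)
    criteria = [
        ("social_security_or_pension", coverage),
        ("health_access", None if record.get("health_access") is None
         else record.get("health_access") == 1),
    ]
    if thresholds.institutional_support_required:
        supp = record.get("institutional_support")
        criteria.append(("institutional_support", None if supp is None else supp == 1))
    return _finish("political_env", criteria, None)


def classify_participation(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """Participates in recreational activities and volunteers at least monthly."""
    criteria = [
        ("recreation", None if record.get("recreation") is None
         else record.get("recreation") == 1),
        ("volunteer_monthly", None if record.get("volunteer_monthly") is None
         else record.get("volunteer_monthly") == 1),
    ]
    return _finish("participation", criteria, None)


def classify_support(record: SurveyRecord, thresholds: Thresholds) -> DomainScore:
    """Receives or provides support from/to family or friends (disjunction)."""
    received, provided = record.get("support_received"), record.get("support_provided")
    if received is None and provided is None:
        met = None
    else:
        met = (received == 1) or (provided == 1)
    return _finish("support", [("receives_or_provides_support", met)], None)


CLASSIFIERS = {
    "physiological": classify_physiological,
    "geriatric_syndromes": classify_geriatric_syndromes,
    "risk_factors": classify_risk_factors,
    "physical": classify_physical,
    "cognitive": classify_cognitive,
    "psychological": classify_psychological,
    "social_welfare": classify_social_welfare,
    "political_env": classify_political_env,
    "participation": classify_participation,
    "support": classify_support,
}


def score_person(record: SurveyRecord, thresholds: Thresholds | None = None,
                 model: tuple[DomainSpec, ...] = DOMAIN_MODEL) -> PersonProfile:
    """Evaluate all ten domains for one respondent.

    Non-evaluable domains (all inputs missing) are flagged, never imputed;
    a record with more than ``thresholds.max_non_evaluable`` such domains is
    flagged for exclusion from clustering.
    """
    thresholds = thresholds or Thresholds()
    scores = [CLASSIFIERS[spec.domain_id](record, thresholds) for spec in model]
    n_bad = sum(1 for s in scores if not s.evaluable)
    return PersonProfile(record.record_id, scores, excluded=n_bad > thresholds.max_non_evaluable)


def score_cohort(records, thresholds: Thresholds | None = None) -> list[PersonProfile]:
    thresholds = thresholds or Thresholds()
    return [score_person(r, thresholds) for r in records]


def profiles_to_frame(profiles: list[PersonProfile]):
    """Scored profiles as a DataFrame: id + 10 scores + 10 classes + excluded."""
    import pandas as pd

    rows = []
    for p in profiles:
        row = {"record_id": p.record_id, "excluded": p.excluded}
        for s in p.scores:
            row[f"score_{s.domain_id}"] = s.score if s.evaluable else None
            row[f"class_{s.domain_id}"] = s.cls if s.evaluable else None
        rows.append(row)
    return pd.DataFrame(rows)
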