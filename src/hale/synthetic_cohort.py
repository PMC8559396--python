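"""SABE-like synthetic cohorts with known ground truth.

The generator is latent-state-first: demographics are drawn from declared
margins, a latent healthy / less-healthy state is drawn from a logistic
model whose covariate effects are specified as odds ratios (intercept
calibrated so the marginal prevalence matches a target), and the raw
domain indicators are then drawn so that the published classification
rules reproduce the intended per-domain criteria pattern exactly. This
gives exact ground truth (latent state + intended domain scores) for
cluster-recovery and parameter-recovery experiments.

A single latent factor is the only dependence between domains; the
``decoupled`` set (by default the risk-factors domain) is drawn
identically for both latent states, mirroring the one domain where the
two groups do not separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .domain_scoring import DOMAIN_IDS, DOMAIN_MODEL, Thresholds, _round_half_up
from .survey_io import SurveyRecord, VariableDictionary
from .variables import (
    DISEASES,
    N_PERF_ITEMS,
    PERF_ITEMS,
    default_dictionary,
)

__all__ = [
    "CovariateEffect",
    "DomainSignal",
    "WeightModel",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "generate_cohort_frame",
    "inject_missingness",
    "frame_to_records",
]

#: published weighted demographic margins (percent of the weighted total,
#: including the missing share) used for the default cohort
TABLE2_PERCENTS = {
    "sex": {"woman": 56.66, "man": 43.12},
    "age_group": {"65-74": 52.89, "75-84": 29.11, "85+": 8.47},
    "area": {"urban": 65.1, "rural": 34.9},
    "ethnicity": {"mestizo": 64.05, "white": 13.18, "indigenous": 10.43,
                  "mulatto": 3.40, "afro_ecuadorian": 3.36, "other": 1.40},
    "education": {"none": 1.69, "literacy_center": 2.19, "kindergarten": 0.31,
                  "primary": 56.09, "high_school": 9.21, "college": 2.65,
                  "postgraduate": 0.25},
}

TABLE2_MISSING_RATES = {
    "sex": 0.0022,
    "age_group": 0.0953,
    "ethnicity": 0.0418,
    "education": 0.2762,
}

#: weighted row totals of the published healthy/less-healthy cross-tables,
#: used as margins for the outcome-perception variables
HEALTH_TOTALS = {"bad": 155_774.0, "regular": 421_008.0, "good": 159_064.0,
                 "very_good": 18_924.0, "excellent": 7_850.0}
SATISFACTION_TOTALS = {1: 637_710.0, 0: 123_070.0}
POVERTY_TOTALS = {0: 441_196.0, 1: 322_234.0}

POPULATION_TOTAL = 898_152.0


@dataclass(frozen=True)
class CovariateEffect:
    """Odds ratio of one covariate level (vs its reference) on the latent state."""

    variable: str
    level: object
    reference: object
    odds_ratio: float

    def __post_init__(self) -> None:
        if not (self.odds_ratio > 0):
            raise ValueError(f"odds ratio must be positive, got {self.odds_ratio}")


@dataclass(frozen=True)
class DomainSignal:
    """Intended score distribution of one domain on the 0-10 scale."""

    healthy_mean: float = 8.5
    gap: float = 3.5  # healthy minus less-healthy mean
    sd: float = 1.5  # per-person noise on the intended mean

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError("noise sd must be positive")


@dataclass(frozen=True)
class WeightModel:
    kind: str = "lognormal"  # unit | lognormal
    sigma: float = 0.6
    total: float = POPULATION_TOTAL  # weights are rescaled to this sum

    def __post_init__(self) -> None:
        if self.kind not in ("unit", "lognormal"):
            raise ValueError(f"unknown weight model {self.kind!r}")
        if self.kind == "lognormal" and not (self.total > 0):
            raise ValueError("population total must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort draw."""

    n: int = 1797
    seed: int = 0
    margins: dict = field(default_factory=dict)  # variable -> {code: prob}
    pi: float = 0.5315  # marginal latent healthy prevalence
    effects: tuple = ()  # CovariateEffect, ...
    signals: dict = field(default_factory=dict)  # domain -> DomainSignal
    decoupled: frozenset = frozenset({"risk_factors"})
    missingness: dict = field(default_factory=dict)  # variable -> MCAR rate
    weights: WeightModel = field(default_factory=WeightModel)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0.0 < self.pi < 1.0):
            raise ValueError("baseline prevalence must lie in (0, 1)")
        for variable, margin in self.margins.items():
            total = sum(margin.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"margins for {variable!r} sum to {total}, not 1")
        for domain in self.decoupled:
            if domain not in DOMAIN_IDS:
                raise ValueError(f"unknown decoupled domain {domain!r}")
        for variable, rate in self.missingness.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missingness rate for {variable!r} must be in [0,1)")

    def signal_for(self, domain: str) -> DomainSignal:
        return self.signals.get(domain, DomainSignal())


def _renormalize(percents: dict) -> dict:
    total = sum(percents.values())
    return {code: value / total for code, value in percents.items()}


def default_spec() -> CohortSpec:
    """The default study conditions: n=1797 respondents expanding to 898,152
    population persons, published demographic margins (renormalized over
    non-missing), latent healthy prevalence 53.15%, the published bivariate
    odds ratios as generating covariate effects, the risk-factors domain
    decoupled from the latent state, and the published missing-value shares."""
    margins = {var: _renormalize(pcts) for var, pcts in TABLE2_PERCENTS.items()}
    margins["perceived_health"] = _renormalize(HEALTH_TOTALS)
    margins["life_satisfaction"] = _renormalize(SATISFACTION_TOTALS)
    margins["income_poverty"] = _renormalize(POVERTY_TOTALS)
    effects = (
        CovariateEffect("sex", "woman", "man", 0.58),
        CovariateEffect("age_group", "75-84", "65-74", 0.78),
        CovariateEffect("age_group", "85+", "65-74", 0.33),
        CovariateEffect("area", "rural", "urban", 0.71),
        CovariateEffect("education", "none", "primary", 0.57),
        CovariateEffect("education", "literacy_center", "primary", 0.28),
        CovariateEffect("education", "kindergarten", "primary", 0.65),
        CovariateEffect("education", "high_school", "primary", 2.61),
        CovariateEffect("education", "college", "primary", 7.11),
        CovariateEffect("education", "postgraduate", "primary", 7.11),
        CovariateEffect("perceived_health", "excellent", "bad", 28.49),
        CovariateEffect("perceived_health", "very_good", "bad", 8.67),
        CovariateEffect("perceived_health", "good", "bad", 7.48),
        CovariateEffect("perceived_health", "regular", "bad", 3.02),
        CovariateEffect("life_satisfaction", 0, 1, 0.23),
        CovariateEffect("income_poverty", 1, 0, 0.44),
    )
    return CohortSpec(
        n=1797,
        seed=0,
        margins=margins,
        pi=0.5315,
        effects=effects,
        missingness=dict(TABLE2_MISSING_RATES),
        weights=WeightModel("lognormal", 0.6, POPULATION_TOTAL),
    )


def spec_to_yaml(spec: CohortSpec, path=None) -> str | None:
    """Serialize a CohortSpec as YAML (inverse of :func:`spec_from_yaml`)."""
    import yaml

    payload = {
        "n": spec.n,
        "seed": spec.seed,
        "pi": spec.pi,
        "margins": {v: {str(k): float(p) for k, p in m.items()}
                    for v, m in spec.margins.items()},
        "effects": [
            {"variable": e.variable, "level": e.level, "reference": e.reference,
             "odds_ratio": e.odds_ratio}
            for e in spec.effects
        ],
        "signals": {d: {"healthy_mean": s.healthy_mean, "gap": s.gap, "sd": s.sd}
                    for d, s in spec.signals.items()},
        "decoupled": sorted(spec.decoupled),
        "missingness": dict(spec.missingness),
        "weights": {"kind": spec.weights.kind, "sigma": spec.weights.sigma,
                    "total": spec.weights.total},
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is None:
        return text
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return None


def spec_from_yaml(source) -> CohortSpec:
    import yaml

    if hasattr(source, "read"):
        payload = yaml.safe_load(source)
    else:
        try:
            with open(source, "r", encoding="utf-8") as fh:
                payload = yaml.safe_load(fh)
        except (OSError, ValueError):
            payload = yaml.safe_load(source)
    base = default_spec()
    margins = payload.get("margins")
    # binary-variable margin keys round-trip through YAML as strings
    fixed_margins = {}
    for variable, margin in (margins or base.margins).items():
        fixed = {}
        for code, prob in margin.items():
            key = int(code) if isinstance(code, str) and code in ("0", "1") else code
            fixed[key] = float(prob)
        fixed_margins[variable] = fixed
    effects = tuple(
        CovariateEffect(e["variable"], e["level"], e["reference"], float(e["odds_ratio"]))
        for e in payload.get("effects", [])
    ) if "effects" in payload else base.effects
    signals = {
        d: DomainSignal(**s) for d, s in payload.get("signals", {}).items()
    }
    weights = payload.get("weights")
    return CohortSpec(
        n=int(payload.get("n", base.n)),
        seed=int(payload.get("seed", base.seed)),
        margins=fixed_margins,
        pi=float(payload.get("pi", base.pi)),
        effects=effects,
        signals=signals,
        decoupled=frozenset(payload.get("decoupled", base.decoupled)),
        missingness=payload.get("missingness", dict(base.missingness)),
        weights=WeightModel(**weights) if weights else base.weights,
    )


def _calibrate_intercept(eta: np.ndarray, pi: float) -> float:
    """Bisect the intercept so the mean latent-healthy probability equals pi."""
    lo, hi = -35.0, 35.0
    f = lambda a: float(np.mean(expit(a + eta))) - pi
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("infeasible odds-ratio combination: calibrated prevalence "
                         "cannot reach the target within (0, 1)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def _draw_categorical(rng, margin: dict, n: int) -> np.ndarray:
    codes = list(margin.keys())
    probs = np.array([margin[c] for c in codes], dtype=float)
    idx = rng.choice(len(codes), size=n, p=probs / probs.sum())
    return np.array(codes, dtype=object)[idx]

# --- mapping intended criterion patterns to raw survey indicators ---------


def _fill_physiological(rng, frame, met):
    for j, disease in enumerate(DISEASES):
        ok = met[:, j]
        absent = rng.random(len(ok)) < 0.75
        dx = np.where(ok & absent, 0, 1)
        controlled = np.where(dx == 1, np.where(ok, 1, 0), 0)
        frame[f"dx_{disease}"] = dx.astype(int)
        frame[f"dx_{disease}_controlled"] = controlled.astype(int)


def _fill_geriatric(rng, frame, met, thr: Thresholds):
    n = met.shape[0]
    frame["med_count"] = np.where(met[:, 0], rng.integers(0, thr.polypharmacy_cut, n),
                                  rng.integers(thr.polypharmacy_cut, thr.polypharmacy_cut + 6, n))
    frame["urinary_incontinence"] = (~met[:, 1]).astype(int)
    frame["fecal_incontinence"] = (~met[:, 2]).astype(int)
    frame["falls_count"] = np.where(met[:, 3], rng.integers(0, thr.falls_cut, n),
                                    rng.integers(thr.falls_cut, thr.falls_cut + 4, n))


def _fill_risk(rng, frame, met, thr: Thresholds):
    n = met.shape[0]
    frame["systolic_bp"] = np.where(met[:, 0], rng.uniform(100, thr.systolic_cut, n),
                                    rng.uniform(thr.systolic_cut + 2, 200, n))
    frame["diastolic_bp"] = np.where(met[:, 0], rng.uniform(60, thr.diastolic_cut, n),
                                     rng.uniform(75, 105, n))
    frame["fasting_glucose"] = np.where(met[:, 1], rng.uniform(75, thr.glucose_cut - 1, n),
                                        rng.uniform(thr.glucose_cut, 250, n))
    frame["bmi"] = np.where(met[:, 2], rng.uniform(19, thr.bmi_cut - 0.5, n),
                            rng.uniform(thr.bmi_cut, 45, n))
    frame["lipids_abnormal"] = (~met[:, 3]).astype(int)
    frame["alcohol_days_week"] = np.where(
        met[:, 4], rng.choice([0, 1], size=n, p=[0.7, 0.3]), rng.integers(2, 8, n))
    frame["tobacco_use"] = (~met[:, 5]).astype(int)
    frame["physically_active"] = met[:, 6].astype(int)


def _fill_physical(rng, frame, met):
    for j, item in enumerate(PERF_ITEMS):
        frame[item] = met[:, j].astype(int)
    frame["katz_disability"] = (~met[:, N_PERF_ITEMS]).astype(int)


def _fill_cognitive(rng, frame, met, thr: Thresholds):
    n = met.shape[0]
    frame["dementia_dx"] = (~met[:, 0]).astype(int)
    cut = thr.minimental_effective_cut
    frame["minimental"] = np.where(met[:, 1], rng.integers(cut, 20, n),
                                   rng.integers(0, cut, n))


def _fill_psychological(rng, frame, met, thr: Thresholds):
    n = met.shape[0]
    frame["abuse_physical"] = (~met[:, 0]).astype(int)
    frame["abuse_sexual"] = (~met[:, 1]).astype(int)
    frame["abuse_psychological"] = (~met[:, 2]).astype(int)
    # printed depression rule: depressed when yesavage <= cut
    frame["yesavage"] = np.where(met[:, 3], rng.integers(thr.yesavage_cut + 1, 16, n),
                                 rng.integers(0, thr.yesavage_cut + 1, n))


def _fill_social_welfare(rng, frame, met, thr: Thresholds):
    n = met.shape[0]
    frame["negligence"] = (~met[:, 0]).astype(int)
    frame["economic_violence"] = (~met[:, 1]).astype(int)
    cut = thr.gijon_effective_cut
    frame["gijon"] = np.where(met[:, 2], rng.integers(5, cut + 1, n),
                              rng.integers(cut + 1, 21, n))


def _fill_political(rng, frame, met):
    n = met.shape[0]
    which = rng.choice(3, size=n, p=[0.45, 0.35, 0.20])  # ss only / pension only / both
    frame["social_security"] = (met[:, 0] & (which != 1)).astype(int)
    frame["pension"] = (met[:, 0] & (which != 0)).astype(int)
    frame["health_access"] = met[:, 1].astype(int)
    frame["institutional_support"] = met[:, 2].astype(int)


def _fill_participation(rng, frame, met):
    frame["recreation"] = met[:, 0].astype(int)
    frame["volunteer_monthly"] = met[:, 1].astype(int)


def _fill_support(rng, frame, met):
    n = met.shape[0]
    which = rng.choice(3, size=n, p=[0.5, 0.25, 0.25])  # receives / provides / both
    frame["support_received"] = (met[:, 0] & (which != 1)).astype(int)
    frame["support_provided"] = (met[:, 0] & (which != 0)).astype(int)


_FILLERS = {
    "physiological": lambda rng, fr, met, thr: _fill_physiological(rng, fr, met),
    "geriatric_syndromes": _fill_geriatric,
    "risk_factors": _fill_risk,
    "physical": lambda rng, fr, met, thr: _fill_physical(rng, fr, met),
    "cognitive": _fill_cognitive,
    "psychological": _fill_psychological,
    "social_welfare": _fill_social_welfare,
    "political_env": lambda rng, fr, met, thr: _fill_political(rng, fr, met),
    "participation": lambda rng, fr, met, thr: _fill_participation(rng, fr, met),
    "support": lambda rng, fr, met, thr: _fill_support(rng, fr, met),
}


def generate_cohort_frame(spec: CohortSpec,
                          thresholds: Thresholds | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized generation; returns (cohort frame, ground-truth frame).

    The cohort frame has one column per dictionary variable plus
    ``record_id`` and ``weight``; the truth frame records the latent state
    and the intended per-domain scores for every record id exactly once.
    """
    thresholds = thresholds or Thresholds()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    frame = pd.DataFrame({"record_id": [f"r{i:06d}" for i in range(n)]})

    # demographics and outcome-perception variables from the margins
    for variable, margin in spec.margins.items():
        frame[variable] = _draw_categorical(rng, margin, n)

    # latent healthy state from the logistic model with calibrated intercept
    eta = np.zeros(n)
    for effect in spec.effects:
        if effect.variable not in frame.columns:
            raise ValueError(f"effect on undrawn variable {effect.variable!r}")
        eta += math.log(effect.odds_ratio) * \
            (frame[effect.variable].to_numpy(dtype=object) == effect.level)
    alpha = _calibrate_intercept(eta, spec.pi)
    p_healthy = expit(alpha + eta)
    healthy = rng.random(n) < p_healthy

    # intended criteria per domain, then raw indicators realizing them
    truth = pd.DataFrame({"record_id": frame["record_id"], "latent_healthy": healthy.astype(int)})
    for domain_spec in DOMAIN_MODEL:
        domain = domain_spec.domain_id
        signal = spec.signal_for(domain)
        if domain in spec.decoupled:
            mu = np.full(n, signal.healthy_mean - signal.gap / 2.0)
        else:
            mu = np.where(healthy, signal.healthy_mean, signal.healthy_mean - signal.gap)
        # intended score ~ N(mu, sd) on the 0-10 scale, discretized to a
        # met-criteria count; which criteria are met is uniform at random
        c = domain_spec.n_criteria
        intended = np.clip(mu + rng.normal(0.0, signal.sd, n), 0.0, 10.0)
        met_count = np.clip(np.floor(intended * c / 10.0 + 0.5), 0, c).astype(int)
        u = rng.random((n, c))
        ranks = np.argsort(np.argsort(u, axis=1), axis=1)
        met = ranks < met_count[:, None]
        _FILLERS[domain](rng, frame, met, thresholds)
        met_count = met.sum(axis=1)
        truth[f"score_{domain}"] = [
            _round_half_up(10.0 * m / domain_spec.n_criteria) for m in met_count
        ]

    # expansion weights
    if spec.weights.kind == "unit":
        frame["weight"] = 1.0
    else:
        w = rng.lognormal(mean=0.0, sigma=spec.weights.sigma, size=n)
        frame["weight"] = w * (spec.weights.total / w.sum())

    # MCAR missingness on the configured variables (derived substream)
    if spec.missingness:
        mask_rng = np.random.default_rng(spec.seed + 1)
        for variable in sorted(spec.missingness):
            rate = spec.missingness[variable]
            if rate > 0:
                mask = mask_rng.random(n) < rate
                frame[variable] = frame[variable].astype(object)
                frame.loc[mask, variable] = None
    return frame, truth


def frame_to_records(frame: pd.DataFrame,
                     dictionary: VariableDictionary | None = None) -> list[SurveyRecord]:
    dictionary = dictionary or default_dictionary()
    names = [n for n in dictionary.names if n in frame.columns]
    records = []
    for row in frame.to_dict("records"):
        values = {}
        for name in names:
            value = row[name]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                values[name] = None
            elif dictionary[name].kind in ("binary", "count"):
                values[name] = int(value)
            elif dictionary[name].kind == "real":
                values[name] = float(value)
            else:
                values[name] = value
        records.append(SurveyRecord(str(row["record_id"]), float(row["weight"]), values))
    return records


def generate_cohort(spec: CohortSpec,
                    thresholds: Thresholds | None = None
                    ) -> tuple[list[SurveyRecord], pd.DataFrame]:
    """Generate a cohort (records + ground-truth table), deterministic by seed."""
    frame, truth = generate_cohort_frame(spec, thresholds)
    return frame_to_records(frame), truth


def inject_missingness(records: list[SurveyRecord], rates: dict, seed: int) -> list[SurveyRecord]:
    """Mask values completely at random at the stated per-variable rates.

    The mask depends only on (seed, variable, record order), so re-applying
    the same rates and seed masks the same cells and is a no-op on an
    already-masked cohort.
    """
    for variable, rate in rates.items():
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"missingness rate for {variable!r} must be in [0,1), got {rate}")
    rng = np.random.default_rng(seed)
    n = len(records)
    out = [SurveyRecord(r.record_id, r.weight, dict(r.values)) for r in records]
    for variable in sorted(rates):
        rate = rates[variable]
        mask = rng.random(n) < rate
        if rate == 0:
            continue
        for record, hit in zip(out, mask):
            if hit and variable in record.values:
                record.values[variable] = None
    return out
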