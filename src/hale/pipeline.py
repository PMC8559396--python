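"""End-to-end pipeline: simulate (or load) -> score -> cluster -> regress ->
report, with a JSON run manifest so any run can be replayed byte-identically.

Artifacts written to the output directory:

* ``profiles.csv``   — per-record domain scores and classes
* ``model.json``     — fitted two-step cluster model (sufficient statistics)
* ``radar.csv``      — weighted per-domain means per group + Welch tests
* ``radar.svg``      — radar chart of the two groups over the ten domains
* ``table2.csv``     — weighted demographic descriptives
* ``table3.csv``     — demographics cross-tabulated against the two groups
* ``or_table.csv``   — bivariate and multivariate odds-ratio tables
* ``manifest.json``  — seed, configuration and artifact checksums
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .domain_scoring import DOMAIN_IDS, Thresholds, profiles_to_frame, score_cohort
from .survey_io import (
    VariableDictionary,
    describe_cohort,
    read_cohort,
    records_to_frame,
    write_cohort,
)
from .survey_logistic import bivariate_table, multivariate_table, or_table_frame
from .synthetic_cohort import default_spec, generate_cohort, spec_from_yaml
from .twostep_cluster import (
    HEALTHY_LABEL,
    compare_domains,
    fit_two_step,
)
from .variables import default_dictionary

__all__ = ["RunConfig", "run_pipeline", "render_radar", "replay_manifest"]

#: regression variable set with the published reference categories
REGRESSION_VARIABLES = ["sex", "age_group", "area", "ethnicity", "education",
                        "perceived_health", "life_satisfaction", "income_poverty"]
REFERENCES = {"sex": "man", "age_group": "65-74", "area": "urban",
              "ethnicity": "mestizo", "education": "primary",
              "perceived_health": "bad", "life_satisfaction": 1,
              "income_poverty": 0}
DESCRIPTIVE_VARIABLES = ["sex", "age_group", "area", "ethnicity", "education"]


@dataclass
class RunConfig:
    """Paths, seed and flags of one pipeline run."""

    output_dir: str
    seed: int = 0
    cohort_path: str | None = None  # None -> simulate the default cohort
    spec_path: str | None = None  # cohort spec YAML when simulating
    dictionary_path: str | None = None
    thresholds_path: str | None = None
    force_k: int = 2
    selection_p_cut: float = 0.05
    include_missing_category: bool = False
    continuity_correction: bool = False


def render_radar(comparison_table: pd.DataFrame, path=None):
    """Radar chart: ten axes scaled 0-10, one polygon per group.

    Axis order follows the canonical domain order of the person profiles.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    domains = list(comparison_table.index)
    angles = np.linspace(0, 2 * np.pi, len(domains), endpoint=False)
    angles_closed = np.concatenate([angles, angles[:1]])

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    for column, label in (("mean_healthy", "healthy ageing group"),
                          ("mean_less_healthy", "less healthy ageing group")):
        vals = comparison_table[column].to_numpy(dtype=float)
        vals_closed = np.concatenate([vals, vals[:1]])
        ax.plot(angles_closed, vals_closed, label=label)
        ax.fill(angles_closed, vals_closed, alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(domains, fontsize=8)
    ax.set_ylim(0, 10)
    ax.set_yticks([0, 2, 4, 6, 8, 10])
    ax.legend(loc="lower center", bbox_to_anchor=(0.5, -0.15))
    if path is not None:
        fig.savefig(path, format="svg", bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def _weighted_crosstab(frame: pd.DataFrame, variables: list[str],
                       group_col: str, weight_col: str = "weight") -> pd.DataFrame:
    """Per-variable weighted counts and row percents by group (healthy first)."""
    rows = []
    for var in variables:
        for level, chunk in frame.groupby(var, dropna=False, sort=False):
            w = chunk[weight_col]
            healthy = float(w[chunk[group_col] == 1].sum())
            less = float(w[chunk[group_col] == 0].sum())
            total = healthy + less
            rows.append({
                "variable": var,
                "level": "Missing" if pd.isna(level) else str(level),
                "healthy_weighted_n": healthy,
                "healthy_row_pct": 100 * healthy / total if total else 0.0,
                "less_healthy_weighted_n": less,
                "less_healthy_row_pct": 100 * less / total if total else 0.0,
            })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns {artifact name: path}. Idempotent for a
    given configuration and seed."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = (default_dictionary() if config.dictionary_path is None
                  else VariableDictionary.from_yaml(config.dictionary_path))
    thresholds = (Thresholds() if config.thresholds_path is None
                  else Thresholds.from_yaml(config.thresholds_path))

    # 1. cohort
    if config.cohort_path is not None:
        records = read_cohort(config.cohort_path, dictionary)
    else:
        spec = (spec_from_yaml(config.spec_path) if config.spec_path
                else default_spec())
        spec = dataclasses.replace(spec, seed=config.seed)
        records, _truth = generate_cohort(spec, thresholds)
        write_cohort(records, out / "cohort.csv", dictionary)

    # 2. scoring
    profiles = score_cohort(records, thresholds)
    pframe = profiles_to_frame(profiles)
    pframe.to_csv(out / "profiles.csv", index=False)

    # 3. clustering on complete, non-excluded profiles
    usable = [i for i, p in enumerate(profiles) if p.complete and not p.excluded]
    X = np.array([[profiles[i].scores[j].score for j in range(len(DOMAIN_IDS))]
                  for i in usable], dtype=float)
    weights = np.array([records[i].weight for i in usable], dtype=float)
    model = fit_two_step(X, feature_names=DOMAIN_IDS, force_k=config.force_k,
                         seed=config.seed + 1)
    model.to_json(out / "model.json")

    comparison = compare_domains(model, X, weights)
    comparison.table.to_csv(out / "radar.csv")
    render_radar(comparison.table, out / "radar.svg")

    # 4. group flag joined back to the cohort frame
    frame = records_to_frame(records, dictionary)
    assignments = model.assignments(X.shape[0])
    healthy_id = next(cid for cid, lab in model.label_map.items()
                      if lab == HEALTHY_LABEL)
    group = pd.Series(np.nan, index=frame.index)
    group.iloc[np.asarray(usable)] = (assignments == healthy_id).astype(float)
    frame["healthy_group"] = group

    # 5. descriptive tables
    describe_cohort(records, DESCRIPTIVE_VARIABLES, dictionary).to_csv(out / "table2.csv")
    _weighted_crosstab(frame.dropna(subset=["healthy_group"]),
                       DESCRIPTIVE_VARIABLES + ["perceived_health",
                                                "life_satisfaction", "income_poverty"],
                       "healthy_group").to_csv(out / "table3.csv", index=False)

    # 6. regression tables
    bivariate = []
    for var in REGRESSION_VARIABLES:
        bivariate.extend(bivariate_table(frame, var, REFERENCES[var]))
    adjusted, info = multivariate_table(frame, REGRESSION_VARIABLES, REFERENCES,
                                        selection_p_cut=config.selection_p_cut)
    or_frame = or_table_frame(bivariate + adjusted)
    or_frame["analysis"] = ["bivariate"] * len(bivariate) + \
        ["multivariate"] * len(adjusted)
    or_frame.to_csv(out / "or_table.csv", index=False)

    # 7. manifest
    artifacts = {name: str(out / name) for name in
                 ["profiles.csv", "model.json", "radar.csv", "radar.svg",
                  "table2.csv", "table3.csv", "or_table.csv"]}
    manifest = {
        "package": "hale",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "multivariate": info,
        "checksums": {name: _sha256(Path(path)) for name, path in artifacts.items()
                      if not name.endswith(".svg")},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    artifacts["manifest.json"] = str(out / "manifest.json")
    return artifacts


def replay_manifest(manifest_path, output_dir) -> dict:
    """Re-run the configuration recorded in a manifest into a new directory."""
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    config = RunConfig(**{**manifest["config"], "output_dir": str(output_dir)})
    return run_pipeline(config)
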