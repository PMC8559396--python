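"""Expansion-weighted association tables: crude odds ratios from weighted
contingency tables and weighted logistic regressions.

Point estimates use weighted maximum likelihood (IRLS). Standard errors use
a weights-only sandwich (robust) covariance with weights normalized to the
record count, an approximation to full complex-sample variance when the
design's strata/PSU identifiers are unavailable — only the expansion factor
is modelled. For a single categorical covariate the weighted-logistic odds
ratios equal the weighted cross-product odds ratios exactly (the saturated-
model identity), which is how bivariate tables relate to the underlying
weighted 2x2 cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

__all__ = [
    "ORResult",
    "FitResult",
    "crude_or",
    "weighted_fit",
    "bivariate_table",
    "multivariate_table",
    "or_table_frame",
]

Z95 = stats.norm.ppf(0.975)
SEPARATION_BOUND = 15.0  # |log-odds| beyond this flags (quasi-)separation


@dataclass
class ORResult:
    """One contrast: level vs reference, with OR, 95% CI, p and (optionally)
    the weighted 2x2 cells (a, b, c, d) = (healthy@level, less@level,
    healthy@ref, less@ref)."""

    variable: str
    level: str
    reference: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    cells: tuple | None = None
    method: str = "weighted_logistic"
    reliable: bool = True

    def __post_init__(self) -> None:
        if self.cells is not None:
            a, b, c, d = self.cells
            expected = (a / b) / (c / d)
            if not np.isclose(self.odds_ratio, expected, rtol=1e-6):
                raise ValueError("odds ratio inconsistent with its 2x2 cells")


@dataclass
class FitResult:
    """Weighted logistic fit: coefficients, sandwich covariance, sizes."""

    params: pd.Series
    cov: pd.DataFrame
    n_records: int
    weighted_total: float
    converged: bool
    n_iter: int = 0

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def or_ci_p(self, name: str) -> tuple[float, float, float, float]:
        beta = float(self.params[name])
        se = float(self.se()[name])
        z = beta / se if se > 0 else np.inf * np.sign(beta)
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        return (float(np.exp(beta)), float(np.exp(beta - Z95 * se)),
                float(np.exp(beta + Z95 * se)), float(p))


def crude_or(a: float, b: float, c: float, d: float, *,
             variable: str = "", level: str = "", reference: str = "",
             continuity_correction: bool = False) -> ORResult:
    """Cross-product odds ratio (a/b)/(c/d) with a Woolf CI on the log scale.

    Cells are weighted frequencies: a/b the healthy/less-healthy totals at
    the index level, c/d at the reference level. A zero cell is an error
    unless ``continuity_correction`` adds 0.5 to every cell.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("weighted cells must be nonnegative")
    if np.any(cells == 0):
        if not continuity_correction:
            raise ValueError("zero cell in 2x2 table; enable continuity_correction "
                             "to add 0.5 to every cell")
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return ORResult(variable, level, reference, float(or_),
                    float(np.exp(log_or - Z95 * se)), float(np.exp(log_or + Z95 * se)),
                    float(p), cells=(a, b, c, d), method="crude")


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; aliased column(s): {aliased}")


def weighted_fit(y: np.ndarray, X: np.ndarray, weights: np.ndarray,
                 names: list[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 100) -> FitResult:
    """Weighted logistic maximum likelihood by IRLS.

    Weights are normalized to sum to the record count before fitting so that
    population-scale expansion factors do not deflate the sandwich standard
    errors. Convergence when the largest score component falls below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w_raw = np.asarray(weights, dtype=float)
    if np.any(w_raw <= 0):
        raise ValueError("weights must be positive")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    _check_rank(X, names)

    n = len(y)
    w = w_raw * (n / w_raw.sum())
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -35, 35)
        p = expit(eta)
        score = X.T @ (w * (y - p))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        wls = w * np.clip(p * (1 - p), 1e-10, None)
        H = (X * wls[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # dampen huge steps so separated fits drift rather than explode
        norm = np.max(np.abs(step))
        if norm > 10:
            step *= 10 / norm
        beta = beta + step

    eta = np.clip(X @ beta, -35, 35)
    p = expit(eta)
    wls = w * np.clip(p * (1 - p), 1e-10, None)
    H = (X * wls[:, None]).T @ X
    resid = w * (y - p)
    B = (X * (resid ** 2)[:, None]).T @ X
    Hinv = np.linalg.pinv(H)
    cov = Hinv @ B @ Hinv
    cov = 0.5 * (cov + cov.T)
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_records=n,
        weighted_total=float(w_raw.sum()),
        converged=converged,
        n_iter=it,
    )


def _complete_mask(frame: pd.DataFrame, columns: list[str]) -> np.ndarray:
    mask = np.ones(len(frame), dtype=bool)
    for col in columns:
        vals = frame[col]
        mask &= vals.notna().to_numpy()
    return mask


def _levels_of(series: pd.Series) -> list:
    seen = []
    for v in series:
        if v is not None and v == v and v not in seen:
            seen.append(v)
    return sorted(seen, key=str)


def bivariate_table(frame: pd.DataFrame, variable: str, reference,
                    outcome: str = "healthy_group", weight: str = "weight",
                    ) -> list[ORResult]:
    """Weighted bivariate logistic regression of a binary outcome on one
    categorical variable; one ORResult per non-reference level.

    Point estimates equal the weighted cross-product ORs of the underlying
    2x2 cells (recorded on each result); the CI comes from the sandwich
    covariance of the weighted fit. Records missing the variable or outcome
    are dropped casewise; levels with no outcome variation are dropped with
    a warning.
    """
    mask = _complete_mask(frame, [variable, outcome])
    sub = frame.loc[mask]
    y = sub[outcome].to_numpy(dtype=float)
    w = sub[weight].to_numpy(dtype=float)
    values = sub[variable].to_numpy(dtype=object)

    levels = [lv for lv in _levels_of(sub[variable]) if lv != reference]
    if reference not in set(sub[variable].dropna()):
        raise ValueError(f"reference level {reference!r} absent from {variable!r}")

    usable = []
    for lv in levels:
        ylv = y[values == lv]
        if ylv.size == 0 or ylv.min() == ylv.max():
            warnings.warn(f"level {lv!r} of {variable!r} dropped: no weighted "
                          f"outcome variation", stacklevel=2)
            continue
        usable.append(lv)
    keep = np.isin(values, np.array(usable + [reference], dtype=object))
    y, w, values = y[keep], w[keep], values[keep]

    X = np.column_stack([np.ones(len(y))] +
                        [(values == lv).astype(float) for lv in usable])
    names = ["(intercept)"] + [f"{variable}[{lv}]" for lv in usable]
    fit = weighted_fit(y, X, w, names)

    results = []
    ref_mask = values == reference
    c = float(w[ref_mask & (y == 1)].sum())
    d = float(w[ref_mask & (y == 0)].sum())
    for lv in usable:
        lv_mask = values == lv
        a = float(w[lv_mask & (y == 1)].sum())
        b = float(w[lv_mask & (y == 0)].sum())
        or_, lo, hi, p = fit.or_ci_p(f"{variable}[{lv}]")
        results.append(ORResult(variable, str(lv), str(reference), or_, lo, hi, p,
                                cells=(a, b, c, d),
                                reliable=abs(np.log(or_)) < SEPARATION_BOUND))
    return results


def multivariate_table(frame: pd.DataFrame, variables: list[str], references: dict,
                       outcome: str = "healthy_group", weight: str = "weight",
                       selection_p_cut: float = 0.05) -> tuple[list[ORResult], dict]:
    """Joint weighted logistic fit of the variables that are bivariately
    significant (any level p below the cut), with casewise deletion.

    Returns the adjusted ORResult list and an info dict (selected variables,
    records used / deleted, convergence). Coefficients beyond the separation
    bound are flagged unreliable rather than suppressed, mirroring how very
    sparse cells inflate odds-ratio intervals.
    """
    if len(variables) < 2:
        raise ValueError("need at least two candidate variables")
    selected = []
    for var in variables:
        res = bivariate_table(frame, var, references[var], outcome, weight)
        if any(r.p_value < selection_p_cut for r in res):
            selected.append(var)
    if not selected:
        return [], {"selected": [], "n_used": 0, "n_deleted": int(len(frame))}

    mask = _complete_mask(frame, selected + [outcome])
    sub = frame.loc[mask]
    y = sub[outcome].to_numpy(dtype=float)
    w = sub[weight].to_numpy(dtype=float)

    cols = [np.ones(len(sub))]
    names = ["(intercept)"]
    layout = []
    for var in selected:
        values = sub[var].to_numpy(dtype=object)
        for lv in _levels_of(sub[var]):
            if lv == references[var]:
                continue
            cols.append((values == lv).astype(float))
            names.append(f"{var}[{lv}]")
            layout.append((var, lv))
    X = np.column_stack(cols)
    fit = weighted_fit(y, X, w, names)

    results = []
    for var, lv in layout:
        or_, lo, hi, p = fit.or_ci_p(f"{var}[{lv}]")
        results.append(ORResult(var, str(lv), str(references[var]), or_, lo, hi, p,
                                method="weighted_logistic_adjusted",
                                reliable=abs(np.log(or_)) < SEPARATION_BOUND))
    info = {"selected": selected, "n_used": int(mask.sum()),
            "n_deleted": int((~mask).sum()), "converged": fit.converged}
    return results, info


def or_table_frame(results: list[ORResult]) -> pd.DataFrame:
    """OR results as a tidy DataFrame (one contrast per row)."""
    return pd.DataFrame([
        {
            "variable": r.variable, "level": r.level, "reference": r.reference,
            "odds_ratio": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value, "method": r.method, "reliable": r.reliable,
            "cell_a": r.cells[0] if r.cells else None,
            "cell_b": r.cells[1] if r.cells else None,
            "cell_c": r.cells[2] if r.cells else None,
            "cell_d": r.cells[3] if r.cells else None,
        }
        for r in results
    ])
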