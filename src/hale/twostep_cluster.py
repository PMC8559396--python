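"""Two-step clustering of domain-score profiles.

The classical scalable construction: records are first pre-grouped into
sub-clusters by sequential CF-tree-style insertion (a record joins the
nearest sub-cluster when the log-likelihood distance increase stays below
a threshold, otherwise starts a new one), then the sub-clusters are merged
agglomeratively under the log-likelihood distance

    d(a, b) = xi(a) + xi(b) - xi(a u b),
    xi(s)   = -N_s * sum_k 1/2 * log(sigma_k^2 + sigma_{s,k}^2),

where ``sigma_k^2`` is the overall (model) variance of feature k and
``sigma_{s,k}^2`` the within-sub-cluster variance. The number of clusters
can be chosen by BIC or forced (the published analysis forces two). The
ten 0-10 domain scores are treated as continuous features; clustering is
on unweighted records, expansion weights enter only in reported means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubCluster",
    "ClusterModel",
    "DomainComparison",
    "ll_distance",
    "build_preclusters",
    "default_threshold",
    "agglomerate",
    "select_k",
    "assign",
    "label_healthy",
    "compare_domains",
    "fit_two_step",
]

HEALTHY_LABEL = "healthy_ageing"
LESS_HEALTHY_LABEL = "less_healthy_ageing"


@dataclass
class SubCluster:
    """Sufficient statistics of one (sub-)cluster: N, per-feature sum and
    sum of squares; member row indices are carried for reporting."""

    n: int
    s: np.ndarray
    ss: np.ndarray
    members: list = field(default_factory=list)

    @classmethod
    def from_rows(cls, rows: np.ndarray, members=None) -> "SubCluster":
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return cls(
            n=rows.shape[0],
            s=rows.sum(axis=0),
            ss=(rows ** 2).sum(axis=0),
            members=list(members) if members is not None else [],
        )

    @property
    def mean(self) -> np.ndarray:
        return self.s / self.n

    @property
    def within_var(self) -> np.ndarray:
        v = self.ss / self.n - (self.s / self.n) ** 2
        return np.maximum(v, 0.0)

    def merged(self, other: "SubCluster") -> "SubCluster":
        return SubCluster(self.n + other.n, self.s + other.s, self.ss + other.ss,
                          self.members + other.members)


def _keep_mask(model_variances: np.ndarray) -> np.ndarray:
    keep = np.asarray(model_variances, dtype=float) > 0.0
    if not keep.all():
        warnings.warn("feature(s) with zero overall variance dropped from the "
                      "log-likelihood distance", stacklevel=3)
    if not keep.any():
        raise ValueError("all features have zero overall variance")
    return keep


def _xi(n, s, ss, model_var: np.ndarray) -> float:
    mean = s / n
    wv = np.maximum(ss / n - mean ** 2, 0.0)
    return float(-n * 0.5 * np.log(model_var + wv).sum())


def ll_distance(a: SubCluster, b: SubCluster, model_variances: np.ndarray) -> float:
    """Log-likelihood merge distance; nonnegative and symmetric."""
    mv = np.asarray(model_variances, dtype=float)
    keep = _keep_mask(mv)
    mv = mv[keep]
    d = (_xi(a.n, a.s[keep], a.ss[keep], mv)
         + _xi(b.n, b.s[keep], b.ss[keep], mv)
         - _xi(a.n + b.n, a.s[keep] + b.s[keep], a.ss[keep] + b.ss[keep], mv))
    return max(d, 0.0)


def _merge_distances(counts, sums, sumsqs, other: SubCluster, model_var) -> np.ndarray:
    """Vectorized d(leaf_i, other) over all leaves (arrays stacked by row)."""
    # xi of each leaf
    mean = sums / counts[:, None]
    wv = np.maximum(sumsqs / counts[:, None] - mean ** 2, 0.0)
    xi_leaves = -counts * 0.5 * np.log(model_var + wv).sum(axis=1)
    # xi of the candidate
    xi_other = _xi(other.n, other.s, other.ss, model_var)
    # xi of each merged pair
    nm = counts + other.n
    sm = sums + other.s
    ssm = sumsqs + other.ss
    meanm = sm / nm[:, None]
    wvm = np.maximum(ssm / nm[:, None] - meanm ** 2, 0.0)
    xi_merged = -nm * 0.5 * np.log(model_var + wvm).sum(axis=1)
    return np.maximum(xi_leaves + xi_other - xi_merged, 0.0)


def build_preclusters(profiles: np.ndarray, distance_threshold: float,
                      branching_limit: int = 512,
                      model_variances: np.ndarray | None = None) -> list[SubCluster]:
    """Sequential pre-clustering of complete profiles.

    Each profile joins the nearest existing sub-cluster if the distance
    increase is at most the threshold, else opens a new sub-cluster. If the
    leaf count exceeds ``branching_limit`` the threshold is doubled and the
    pass restarts (mirroring CF-tree rebuilds). Deterministic in input order.
    """
    if not (distance_threshold > 0):
        raise ValueError("distance threshold must be positive")
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("profiles must be a non-empty 2-D array")
    mv_full = np.var(X, axis=0) if model_variances is None else \
        np.asarray(model_variances, dtype=float)
    keep = _keep_mask(mv_full)
    Xk, mv = X[:, keep], mv_full[keep]

    threshold = float(distance_threshold)
    while True:
        counts = np.empty(0, dtype=float)
        sums = np.empty((0, Xk.shape[1]))
        sumsqs = np.empty((0, Xk.shape[1]))
        members: list[list[int]] = []
        overflow = False
        for i, x in enumerate(Xk):
            point = SubCluster(1, x, x ** 2)
            if counts.size:
                dists = _merge_distances(counts, sums, sumsqs, point, mv)
                j = int(np.argmin(dists))
                if dists[j] <= threshold:
                    counts[j] += 1
                    sums[j] += x
                    sumsqs[j] += x ** 2
                    members[j].append(i)
                    continue
            counts = np.append(counts, 1.0)
            sums = np.vstack([sums, x])
            sumsqs = np.vstack([sumsqs, x ** 2])
            members.append([i])
            if len(members) > branching_limit:
                overflow = True
                break
        if not overflow:
            break
        threshold *= 2.0

    # statistics are rebuilt on the full feature set so downstream reporting
    # keeps all domains even when one was dropped from the distance
    return [SubCluster.from_rows(X[m], members=m) for m in members]


def default_threshold(profiles: np.ndarray, seed: int = 0,
                      subsample: int = 200, percentile: float = 25.0,
                      model_variances: np.ndarray | None = None) -> float:
    """25th percentile of pairwise singleton distances on a subsample."""
    X = np.asarray(profiles, dtype=float)
    mv = np.var(X, axis=0) if model_variances is None else np.asarray(model_variances)
    rng = np.random.default_rng(seed)
    if X.shape[0] > subsample:
        X = X[rng.choice(X.shape[0], size=subsample, replace=False)]
    keep = _keep_mask(mv)
    Xk, mvk = X[:, keep], mv[keep]
    # closed form for singletons: d = sum_k log(1 + (xi-yj)^2 / (4 mv_k))
    diff = Xk[:, None, :] - Xk[None, :, :]
    d = np.log1p(diff ** 2 / (4.0 * mvk)).sum(axis=2)
    iu = np.triu_indices(Xk.shape[0], k=1)
    vals = d[iu]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1e-6
    return float(np.percentile(vals, percentile))


@dataclass
class ClusterModel:
    """Fitted two-step clustering: merged clusters, merge history, model
    variances and (after labeling) the healthy-label map."""

    k: int
    clusters: list
    merge_history: list
    model_variances: np.ndarray
    feature_names: tuple
    label_map: dict | None = None

    @property
    def n_clustered(self) -> int:
        return sum(c.n for c in self.clusters)

    def cluster_means(self) -> np.ndarray:
        return np.vstack([c.mean for c in self.clusters])

    def assignments(self, n_rows: int) -> np.ndarray:
        out = np.full(n_rows, -1, dtype=int)
        for cid, cluster in enumerate(self.clusters):
            out[np.asarray(cluster.members, dtype=int)] = cid
        return out

    def to_json(self, path=None) -> str | None:
        payload = {
            "k": self.k,
            "feature_names": list(self.feature_names),
            "model_variances": self.model_variances.tolist(),
            "label_map": self.label_map,
            "merge_history": [[int(i), int(j), float(d)] for i, j, d in self.merge_history],
            "clusters": [
                {"n": c.n, "sum": c.s.tolist(), "sumsq": c.ss.tolist(),
                 "members": list(map(int, c.members))}
                for c in self.clusters
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source) -> "ClusterModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    payload = json.load(fh)
            except OSError:
                payload = json.loads(source)
        clusters = [
            SubCluster(c["n"], np.asarray(c["sum"]), np.asarray(c["sumsq"]),
                       members=list(c["members"]))
            for c in payload["clusters"]
        ]
        label_map = payload["label_map"]
        if label_map is not None:
            label_map = {int(k): v for k, v in label_map.items()}
        return cls(
            k=payload["k"],
            clusters=clusters,
            merge_history=[tuple(h) for h in payload["merge_history"]],
            model_variances=np.asarray(payload["model_variances"], dtype=float),
            feature_names=tuple(payload["feature_names"]),
            label_map=label_map,
        )


def agglomerate(subclusters: list[SubCluster], k: int,
                model_variances: np.ndarray,
                feature_names: tuple = ()) -> ClusterModel:
    """Greedy merge of the minimum-distance pair until k clusters remain.

    Ties are broken by the lexicographically lowest active index pair, so
    the result is deterministic given the input order.
    """
    m = len(subclusters)
    if not (1 <= k <= m):
        raise ValueError(f"k={k} outside 1..{m}")
    mv_full = np.asarray(model_variances, dtype=float)
    keep = _keep_mask(mv_full)
    mv = mv_full[keep]
    active = [SubCluster(c.n, c.s.copy(), c.ss.copy(), list(c.members))
              for c in subclusters]

    counts = np.array([c.n for c in active], dtype=float)
    sums = np.vstack([c.s[keep] for c in active])
    sumsqs = np.vstack([c.ss[keep] for c in active])

    def _xi_vec(cnt, sm, ssq):
        mean = sm / cnt[:, None]
        wv = np.maximum(ssq / cnt[:, None] - mean ** 2, 0.0)
        return -cnt * 0.5 * np.log(mv + wv).sum(axis=1)

    xi = _xi_vec(counts, sums, sumsqs)
    # full pairwise merge-cost matrix via broadcasting
    nm = counts[:, None] + counts[None, :]
    sm = sums[:, None, :] + sums[None, :, :]
    ssm = sumsqs[:, None, :] + sumsqs[None, :, :]
    meanm = sm / nm[..., None]
    wvm = np.maximum(ssm / nm[..., None] - meanm ** 2, 0.0)
    xi_merged = -nm * 0.5 * np.log(mv + wvm).sum(axis=2)
    dist = np.maximum(xi[:, None] + xi[None, :] - xi_merged, 0.0)
    dist[np.tril_indices(m)] = np.inf

    alive = np.ones(m, dtype=bool)
    history = []
    n_alive = m
    while n_alive > k:
        flat = int(np.argmin(dist))  # first minimum = lowest (i, j) pair
        i, j = divmod(flat, m)
        history.append((i, j, float(dist[i, j])))
        active[i] = active[i].merged(active[j])
        counts[i] += counts[j]
        sums[i] += sums[j]
        sumsqs[i] += sumsqs[j]
        alive[j] = False
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        others = np.nonzero(alive)[0]
        others = others[others != i]
        if others.size:
            merged = SubCluster(int(counts[i]), sums[i], sumsqs[i])
            new_d = _merge_distances(counts[others], sums[others], sumsqs[others],
                                     merged, mv)
            dist[i, others[others > i]] = new_d[others > i]
            dist[others[others < i], i] = new_d[others < i]
        n_alive -= 1

    clusters = [active[i] for i in np.nonzero(alive)[0]]
    if not feature_names:
        feature_names = tuple(f"f{i}" for i in range(len(mv_full)))
    return ClusterModel(k=k, clusters=clusters, merge_history=history,
                        model_variances=mv_full, feature_names=tuple(feature_names))


def select_k(subclusters: list[SubCluster], k_max: int,
             model_variances: np.ndarray, force_k: int | None = None) -> int:
    """Choose the cluster count by BIC, or bypass with ``force_k`` (the
    published analysis fixes two clusters).

    BIC(k) = -2 * sum_c xi(c) + m_k * log(n) with m_k = k * 2 * n_features.
    """
    if force_k is not None:
        if force_k < 1:
            raise ValueError("force_k must be >= 1")
        return int(force_k)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    mv = np.asarray(model_variances, dtype=float)
    keep = _keep_mask(mv)
    mvk = mv[keep]
    n_total = sum(c.n for c in subclusters)
    d = int(keep.sum())
    k_max = min(k_max, len(subclusters))

    best_k, best_bic = 1, np.inf
    for k in range(1, k_max + 1):
        model = agglomerate(subclusters, k, mv)
        ll = sum(_xi(c.n, c.s[keep], c.ss[keep], mvk) for c in model.clusters)
        bic = -2.0 * ll + k * 2 * d * np.log(n_total)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


def assign(profile: np.ndarray, model: ClusterModel) -> int:
    """Cluster whose distance increase upon absorbing the profile is minimal;
    ties go to the lower cluster id."""
    x = np.asarray(profile, dtype=float)
    point = SubCluster(1, x, x ** 2)
    dists = [ll_distance(c, point, model.model_variances) for c in model.clusters]
    return int(np.argmin(dists))


def label_healthy(model: ClusterModel) -> dict:
    """Label the cluster with the greater grand mean of domain scores as the
    healthy-ageing group; exact ties are refused."""
    grand = [float(c.mean.mean()) for c in model.clusters]
    order = np.argsort(grand)[::-1]
    if len(grand) >= 2 and grand[order[0]] == grand[order[1]]:
        raise ValueError("exact tie in cluster grand means; label manually")
    label_map = {int(cid): LESS_HEALTHY_LABEL for cid in range(len(grand))}
    label_map[int(order[0])] = HEALTHY_LABEL
    model.label_map = label_map
    return label_map


@dataclass
class DomainComparison:
    """Per-domain weighted cluster means with Welch mean-difference tests."""

    table: pd.DataFrame  # index: domain; columns: mean_healthy, mean_less_healthy,
    #                      diff, statistic, p_value

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _weighted_welch(x1, w1, x2, w2):
    """Welch test on weighted means using effective sample sizes."""
    m1 = np.average(x1, weights=w1)
    m2 = np.average(x2, weights=w2)
    v1 = np.average((x1 - m1) ** 2, weights=w1)
    v2 = np.average((x2 - m2) ** 2, weights=w2)
    n1 = w1.sum() ** 2 / (w1 ** 2).sum()
    n2 = w2.sum() ** 2 / (w2 ** 2).sum()
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    if se2 <= 0:
        return m1, m2, diff, 0.0 if diff == 0 else np.inf, 1.0 if diff == 0 else 0.0
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1) + 1e-300)
    p = 2.0 * stats.t.sf(abs(t), df)
    return m1, m2, diff, float(t), float(p)


def compare_domains(model: ClusterModel, profiles: np.ndarray,
                    weights: np.ndarray | None = None) -> DomainComparison:
    """Weighted per-domain means per cluster and Welch tests (no multiplicity
    adjustment); requires a labeled 2-cluster model."""
    if model.k != 2:
        raise ValueError("domain comparison requires a 2-cluster model")
    if model.label_map is None:
        label_healthy(model)
    X = np.asarray(profiles, dtype=float)
    w = np.ones(X.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    assign_vec = model.assignments(X.shape[0])
    healthy_id = next(cid for cid, lab in model.label_map.items() if lab == HEALTHY_LABEL)
    mask_h = assign_vec == healthy_id
    mask_l = (assign_vec >= 0) & ~mask_h
    rows = []
    for j, name in enumerate(model.feature_names):
        m1, m2, diff, t, p = _weighted_welch(X[mask_h, j], w[mask_h],
                                             X[mask_l, j], w[mask_l])
        rows.append({"domain": name, "mean_healthy": m1, "mean_less_healthy": m2,
                     "diff": diff, "statistic": t, "p_value": p})
    table = pd.DataFrame(rows).set_index("domain")
    return DomainComparison(table)


def fit_two_step(profiles: np.ndarray, feature_names: tuple = (),
                 force_k: int | None = 2, k_max: int = 8,
                 distance_threshold: float | None = None,
                 branching_limit: int = 512, seed: int = 0) -> ClusterModel:
    """Convenience wrapper: threshold -> pre-clusters -> k -> agglomerate -> label."""
    X = np.asarray(profiles, dtype=float)
    mv = np.var(X, axis=0)
    if distance_threshold is None:
        distance_threshold = default_threshold(X, seed=seed, model_variances=mv)
    leaves = build_preclusters(X, distance_threshold, branching_limit, mv)
    k = select_k(leaves, k_max, mv, force_k=force_k)
    model = agglomerate(leaves, k, mv, feature_names or
                        tuple(f"f{i}" for i in range(X.shape[1])))
    if k == 2:
        label_healthy(model)
    return model
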