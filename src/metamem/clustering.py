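"""k-means over hidden-unit activations and per-cluster characterization.

The trained network compresses each participant into h hidden activations;
k-means (Lloyd's algorithm, k-means++ seeding, best of many restarts)
groups participants blindly in that space.  With the study design (two
qualitatively different subgroups of older adults plus a young-typical
group) the solution of interest has k = 3, and clusters are given
canonical labels: cluster 1 is the predominantly young cluster, cluster 2
the older subgroup with the higher mean z-scored associate postdiction
accuracy (the "confident, well-calibrated" profile) and cluster 3 the
remaining older subgroup.

Per-cluster mean profiles of the z-scored inputs and one-way
between-groups ANOVAs per variable (Bonferroni-corrected, with partial
eta squared) identify which measures drive the separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from metamem.datamodel import FeatureMatrix

__all__ = [
    "ClusterSolution",
    "ClusterAnovaRow",
    "kmeans",
    "canonicalize_clusters",
    "cluster_profiles",
    "cluster_feature_anovas",
    "anova_rows_to_frame",
    "composition_table",
]


@dataclass(frozen=True)
class ClusterSolution:
    """Best-of-restarts k-means result; assignments use labels 1..k."""

    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    restarts: int
    seed: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    closest_sq = np.sum((points - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = closest_sq.sum()
        if total == 0.0:
            centroids[j] = points[rng.integers(n)]
        else:
            centroids[j] = points[rng.choice(n, p=closest_sq / total)]
        closest_sq = np.minimum(
            closest_sq, np.sum((points - centroids[j]) ** 2, axis=1)
        )
    return centroids


def _lloyd(
    points: np.ndarray, centroids: np.ndarray, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    prev_inertia = np.inf
    k = centroids.shape[0]
    labels = np.zeros(points.shape[0], dtype=int)
    reseeded = False
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(points.shape[0]), labels].sum())
        # Lloyd iterations cannot increase the objective (re-seeding an
        # emptied centroid is the one step outside that guarantee)
        assert reseeded or inertia <= prev_inertia + 1e-9 * max(1.0, abs(prev_inertia))
        reseeded = False
        for j in range(k):
            members = points[labels == j]
            if members.shape[0] == 0:
                # empty cluster: re-seed its centroid at the point farthest
                # from its current assignment's centroid
                farthest = int(d2[np.arange(points.shape[0]), labels].argmax())
                centroids[j] = points[farthest]
                reseeded = True
            else:
                centroids[j] = members.mean(axis=0)
        if np.isfinite(prev_inertia) and prev_inertia - inertia <= tol * max(
            1.0, abs(prev_inertia)
        ):
            prev_inertia = inertia
            break
        prev_inertia = inertia
    return labels, centroids, prev_inertia


def kmeans(
    points,
    k: int = 3,
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-12,
) -> ClusterSolution:
    """Lloyd's algorithm with k-means++ seeding; returns the best restart.

    ``points`` is the n x h matrix of hidden activations.  The restart
    with the minimal within-cluster sum of squares wins; ties keep the
    earlier restart.  Deterministic under ``seed``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be an n x h matrix")
    n = points.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"need n >= k >= 1, got n = {n}, k = {k}")
    if restarts < 1:
        raise ValueError("restarts must be at least 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(restarts):
        init = _kmeanspp_init(points, k, rng)
        labels, centroids, inertia = _lloyd(points, init.copy(), rng, max_iter, tol)
        if best is None or inertia < best[0]:
            best = (inertia, labels, centroids)
    inertia, labels, centroids = best
    return ClusterSolution(
        assignments=labels + 1,
        centroids=centroids,
        inertia=inertia,
        restarts=restarts,
        seed=seed,
    )


def _young_mask(age_labels) -> np.ndarray:
    arr = np.asarray(age_labels)
    if arr.dtype.kind in "UOS":
        return arr.astype(str) == "young"
    return np.asarray(arr, dtype=float) < 0


def canonicalize_clusters(
    solution: ClusterSolution,
    age_labels,
    features_z: FeatureMatrix,
) -> ClusterSolution:
    """Relabel a k = 3 solution into the canonical 1/2/3 ordering.

    Cluster 1 is the cluster with the highest proportion of younger
    adults; of the remaining two, cluster 2 is the one with the higher
    mean z-scored associate postdiction accuracy.  The relabeling is
    invariant to the arbitrary label order k-means returns.  For k != 3
    the solution is returned unchanged with a warning, since the
    canonical names are defined only for the three-cluster design.
    """
    if solution.k != 3:
        warnings.warn("canonical cluster labels are defined only for k = 3")
        return solution
    young = _young_mask(age_labels)
    if features_z.scale != "zscored":
        raise ValueError("canonicalization requires z-scored features")
    try:
        pacc_col = features_z.column_labels.index("postdiction_accuracy_assoc")
    except ValueError as exc:
        raise ValueError(
            "features must include the associate postdiction-accuracy column"
        ) from exc

    old_labels = sorted(set(solution.assignments))
    frac_young = {
        lab: young[solution.assignments == lab].mean() for lab in old_labels
    }
    first = max(old_labels, key=lambda lab: (frac_young[lab], -lab))
    rest = [lab for lab in old_labels if lab != first]
    pacc_mean = {
        lab: features_z.values[solution.assignments == lab, pacc_col].mean()
        for lab in rest
    }
    second = max(rest, key=lambda lab: (pacc_mean[lab], -lab))
    third = next(lab for lab in rest if lab != second)
    mapping = {first: 1, second: 2, third: 3}

    new_assignments = np.array([mapping[lab] for lab in solution.assignments])
    order = sorted(mapping, key=mapping.get)
    return ClusterSolution(
        assignments=new_assignments,
        centroids=solution.centroids[[lab - 1 for lab in order]],
        inertia=solution.inertia,
        restarts=solution.restarts,
        seed=solution.seed,
    )


def cluster_profiles(features_z: FeatureMatrix, assignments) -> pd.DataFrame:
    """Per-cluster mean and standard error of each z-scored variable.

    Values above zero mean above the sample average for that variable.
    Returns a DataFrame indexed by variable with MultiIndex columns
    (cluster, {mean, se}); the SE of a singleton cluster is NaN.
    """
    assignments = np.asarray(assignments)
    if assignments.shape[0] != features_z.n:
        raise ValueError("assignments do not cover all rows")
    clusters = sorted(set(assignments.tolist()))
    data: dict[tuple[int, str], np.ndarray] = {}
    for lab in clusters:
        block = features_z.values[assignments == lab]
        data[(lab, "mean")] = block.mean(axis=0)
        if block.shape[0] >= 2:
            data[(lab, "se")] = block.std(axis=0, ddof=1) / np.sqrt(block.shape[0])
        else:
            data[(lab, "se")] = np.full(features_z.p, np.nan)
    frame = pd.DataFrame(data, index=list(features_z.column_labels))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["cluster", "stat"])
    return frame


@dataclass(frozen=True)
class ClusterAnovaRow:
    """One-way between-clusters ANOVA for a single input variable."""

    variable: str
    cluster_means: dict[int, float]
    F: float
    df_between: int
    df_within: int
    p_raw: float
    p_bonferroni: float
    partial_eta_squared: float
    significant: bool


def cluster_feature_anovas(
    features: FeatureMatrix,
    assignments,
    m_tests: int | None = None,
    alpha: float = 0.05,
) -> list[ClusterAnovaRow]:
    """One-way independent-measures ANOVA of each variable across clusters.

    Bonferroni correction defaults to m = the number of variables tested
    (18 for the full grid, giving the significance cut p_raw < .0028 at
    alpha = .05).  Partial eta squared is SS_between / (SS_between +
    SS_within).
    """
    assignments = np.asarray(assignments)
    if assignments.shape[0] != features.n:
        raise ValueError("assignments do not cover all rows")
    clusters = sorted(set(assignments.tolist()))
    if len(clusters) < 2:
        raise ValueError("ANOVA needs at least 2 clusters")
    sizes = {lab: int(np.sum(assignments == lab)) for lab in clusters}
    degenerate = [lab for lab, n in sizes.items() if n < 2]
    if degenerate:
        raise ValueError(f"cluster(s) {degenerate} have fewer than 2 members")
    if m_tests is None:
        m_tests = features.p

    n = features.n
    k = len(clusters)
    rows = []
    for j, variable in enumerate(features.column_labels):
        y = features.values[:, j]
        grand = y.mean()
        ssb = sum(
            sizes[lab] * (y[assignments == lab].mean() - grand) ** 2 for lab in clusters
        )
        ssw = sum(
            float(((y[assignments == lab] - y[assignments == lab].mean()) ** 2).sum())
            for lab in clusters
        )
        df_b, df_w = k - 1, n - k
        if ssw == 0.0:
            F = np.inf if ssb > 0 else 0.0
            p = 0.0 if ssb > 0 else 1.0
        else:
            F = (ssb / df_b) / (ssw / df_w)
            p = float(f_dist.sf(F, df_b, df_w))
        rows.append(
            ClusterAnovaRow(
                variable=variable,
                cluster_means={lab: float(y[assignments == lab].mean()) for lab in clusters},
                F=float(F),
                df_between=df_b,
                df_within=df_w,
                p_raw=p,
                p_bonferroni=min(1.0, m_tests * p),
                partial_eta_squared=float(ssb / (ssb + ssw)) if (ssb + ssw) > 0 else 0.0,
                significant=p < alpha / m_tests,
            )
        )
    return rows


def anova_rows_to_frame(rows: list[ClusterAnovaRow]) -> pd.DataFrame:
    """Tabulate :func:`cluster_feature_anovas` output."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "F": [r.F for r in rows],
            "df_between": [r.df_between for r in rows],
            "df_within": [r.df_within for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_bonferroni": [r.p_bonferroni for r in rows],
            "partial_eta_squared": [r.partial_eta_squared for r in rows],
            "significant": [r.significant for r in rows],
        }
    ).set_index("variable")


def composition_table(assignments, age_labels) -> pd.DataFrame:
    """Young/old counts per cluster; marginals equal the group sizes."""
    assignments = np.asarray(assignments)
    young = _young_mask(age_labels)
    clusters = sorted(set(assignments.tolist()))
    return pd.DataFrame(
        {
            "young": [int(np.sum(young & (assignments == lab))) for lab in clusters],
            "old": [int(np.sum(~young & (assignments == lab))) for lab in clusters],
        },
        index=pd.Index(clusters, name="cluster"),
    )
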