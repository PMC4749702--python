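"""Cluster-count selection, k-means fitting, and per-dimension ANOVA F.

Features are z-scored per dimension before any distance computation (the
fractal dimensions live near 1.5-1.8 while entropy spans 0.5-1.0, so raw
Euclidean distances would be dominated by whichever axis happens to have the
widest spread).  The number of clusters is chosen by v-fold cross-validation:
for each candidate k, k-means is fitted on the training folds and held-out
points are scored by their distance to the nearest trained centroid; the scan
stops at the first k whose relative improvement over k-1 falls below a
threshold (default 5%) and returns k-1.  Per-dimension one-way ANOVA F values
report how strongly each measure separates the fitted clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.model_selection import KFold

from .errors import DegenerateInputError

__all__ = ["ClusterModel", "choose_k", "kmeans_fit", "anova_f", "zscore"]


@dataclass
class ClusterModel:
    """A fitted k-means model on z-scored features.

    Cluster indices are relabeled by ascending centroid value on the first
    feature dimension (D0 in the default feature order) for stable reporting.
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    f_values: np.ndarray | None
    seed: int
    n_restarts: int
    inertia: float
    feature_names: tuple[str, ...] = ()


def _as_matrix(features) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=np.float64), tuple(features.columns)
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("features must be a 2-D table (cases x measures)")
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def zscore(x: np.ndarray) -> np.ndarray:
    """Per-column standardization; constant columns map to zeros."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _cv_scores(
    x: np.ndarray, ks: list[int], v: int, seed: int
) -> dict[int, float]:
    """Mean held-out distance to the nearest trained centroid, per k."""
    kf = KFold(n_splits=v, shuffle=True, random_state=seed)
    scores: dict[int, float] = {}
    for k in ks:
        fold_scores = []
        for train, test in kf.split(x):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x[train])
            d = np.linalg.norm(
                x[test][:, None, :] - km.cluster_centers_[None, :, :], axis=2
            ).min(axis=1)
            fold_scores.append(d.mean())
        scores[k] = float(np.mean(fold_scores))
    return scores


def choose_k(
    features,
    v: int = 10,
    k_range=range(1, 11),
    seed: int = 0,
    rel_threshold: float = 0.05,
) -> int:
    """Number of clusters by v-fold cross-validated centroid distance.

    For each k, the mean distance of held-out points to their nearest trained
    centroid is averaged over v folds.  Because splitting even a single
    Gaussian blob improves that score substantially (roughly 20% for the
    first split in two dimensions), raw relative improvements cannot separate
    real cluster structure from the geometric gain of adding centroids; each
    improvement is therefore corrected by the improvement the same procedure
    achieves on an unclustered reference sample (uniform over the z-scored
    data's bounding box, same n, fixed seed), in the spirit of the gap
    statistic.  Scanning k in ascending order, the first k whose corrected
    improvement over k-1 falls below ``rel_threshold`` ends the scan and k-1
    is returned; if every step keeps improving, the largest k wins.
    Deterministic for a fixed seed.
    """
    x, _ = _as_matrix(features)
    n = x.shape[0]
    if not 2 <= v <= n:
        raise ValueError(f"need n >= v >= 2, got n={n}, v={v}")
    x = zscore(x)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    min_train = n - (n // v + (1 if n % v else 0))
    ks = [k for k in ks if k <= max(min_train, 1)]

    rng = np.random.default_rng(seed)
    null = rng.uniform(x.min(axis=0), x.max(axis=0), size=x.shape)
    scores = _cv_scores(x, ks, v, seed)
    null_scores = _cv_scores(null, ks, v, seed)

    def rel_gain(s: dict[int, float], k_prev: int, k: int) -> float:
        return (s[k_prev] - s[k]) / s[k_prev] if s[k_prev] > 0 else 0.0

    chosen = ks[0]
    for k_prev, k in zip(ks, ks[1:]):
        corrected = rel_gain(scores, k_prev, k) - rel_gain(null_scores, k_prev, k)
        if corrected < rel_threshold:
            return k_prev
        chosen = k
    return chosen


def kmeans_fit(
    features, k: int, seed: int = 0, n_restarts: int = 25
) -> ClusterModel:
    """Best-of-restarts k-means on z-scored features.

    Lloyd iterations run to convergence from ``n_restarts`` randomized
    initializations; the assignment with the lowest within-cluster sum of
    squares wins.  Requires k <= n.
    """
    x, names = _as_matrix(features)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    z = zscore(x)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(z)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    assignments = relabel[km.labels_]
    centroids = km.cluster_centers_[order]
    f_values = None
    if k >= 2:
        counts = np.bincount(assignments, minlength=k)
        if counts.min() >= 1 and (counts >= 2).any() and n > k:
            f_values = anova_f(z, assignments)
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        f_values=f_values,
        seed=seed,
        n_restarts=n_restarts,
        inertia=float(km.inertia_),
        feature_names=names,
    )


def anova_f(features, assignments) -> np.ndarray:
    """One-way ANOVA F per feature dimension across clusters.

    F = between-group mean square / within-group mean square.  A dimension
    identical across clusters yields F = 0; perfect separation with zero
    within-group variance yields +inf.
    """
    x, _ = _as_matrix(features)
    groups = np.asarray(assignments)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise DegenerateInputError("ANOVA needs at least two clusters")
    n = x.shape[0]
    sizes = np.array([(groups == g).sum() for g in uniq])
    if sizes.min() < 1 or not (sizes >= 2).any():
        raise DegenerateInputError("each cluster needs a member, one needs two")
    if n - uniq.size < 1:
        raise DegenerateInputError("no within-group degrees of freedom")
    grand = x.mean(axis=0)
    ss_between = np.zeros(x.shape[1])
    ss_within = np.zeros(x.shape[1])
    for g, ng in zip(uniq, sizes):
        xg = x[groups == g]
        mg = xg.mean(axis=0)
        ss_between += ng * (mg - grand) ** 2
        ss_within += ((xg - mg) ** 2).sum(axis=0)
    ms_between = ss_between / (uniq.size - 1)
    ms_within = ss_within / (n - uniq.size)
    f = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        if ms_within[j] > 0:
            f[j] = ms_between[j] / ms_within[j]
        else:
            f[j] = np.inf if ms_between[j] > 0 else 0.0
    return f
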