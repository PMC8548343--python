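"""Connectivity-state decomposition: k-means with the L1 distance.

Pooled windowed FC vectors (all subjects × all windows) are clustered
into k recurring connectivity states with a Lloyd-style k-means using the
L1 (city-block) distance and coordinate-wise-median centroid updates —
the combination that makes the within-cluster L1 inertia non-increasing
per iteration.  Clustering is two-stage: a first pass on per-subject
exemplar windows (local maxima of across-pair FC variance) whose
centroids initialise a single full-data pass.  Model-order diagnostics
(silhouette, elbow/WCSS, Dunn index, all with L1 distances) and
split-half reproducibility complete the module.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples
from sklearn.utils.validation import check_is_fitted

from .windows import WindowedFCSeries

__all__ = [
    "L1KMeans",
    "StatePartition",
    "ClusterValidity",
    "kmeans_l1",
    "two_stage_cluster",
    "cluster_validity",
    "split_half_reproducibility",
    "group_state_medians",
    "match_centroids",
    "exemplar_windows",
]

logger = logging.getLogger(__name__)


class L1KMeans(ClusterMixin, BaseEstimator):
    """K-means with L1 assignment and coordinate-wise-median updates.

    Parameters follow the sklearn KMeans surface: ``n_clusters``,
    ``n_init`` random restarts (best inertia wins), ``max_iter`` Lloyd
    iterations, ``random_state``.  ``init`` may be ``"random"`` (k
    distinct data points) or an explicit (k, P) array, in which case
    ``n_init`` is ignored.  Ties in assignment go to the lowest state
    index; an emptied cluster is reseeded with the point farthest (L1)
    from its current centroid.

    Attributes
    ----------
    cluster_centers_ : ndarray (k, P)
        Coordinate-wise medians of their assigned points at convergence.
    labels_ : ndarray (N,)
        0-based cluster indices.
    inertia_ : float
        Total within-cluster L1 distance.
    inertia_history_ : list of float
        Inertia per Lloyd iteration of the winning restart
        (non-increasing).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        init: str | np.ndarray = "random",
        n_init: int = 10,
        max_iter: int = 500,
        random_state: int | None = 0,
    ):
        self.n_clusters = n_clusters
        self.init = init
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def _lloyd(self, X: np.ndarray, centers: np.ndarray):
        N = X.shape[0]
        labels = np.full(N, -1)
        history: list[float] = []
        for _ in range(self.max_iter):
            D = cdist(X, centers, metric="cityblock")
            new_labels = np.argmin(D, axis=1)  # argmin -> lowest index on ties
            # reseed empty clusters with the worst-fitted point
            for j in range(self.n_clusters):
                if not np.any(new_labels == j):
                    far = int(np.argmax(D[np.arange(N), new_labels]))
                    new_labels[far] = j
                    centers[j] = X[far]
                    D[:, j] = cdist(X, centers[j : j + 1], "cityblock")[:, 0]
            inertia = float(D[np.arange(N), new_labels].sum())
            history.append(inertia)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(self.n_clusters):
                centers[j] = np.median(X[labels == j], axis=0)
        D = cdist(X, centers, metric="cityblock")
        labels = np.argmin(D, axis=1)
        inertia = float(D[np.arange(N), labels].sum())
        history.append(inertia)
        return centers, labels, inertia, history

    def fit(self, X: np.ndarray, y=None) -> "L1KMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty N x P matrix")
        N = X.shape[0]
        if self.n_clusters > N:
            raise ValueError(f"n_clusters={self.n_clusters} > N={N}")
        rng = np.random.default_rng(self.random_state)
        if isinstance(self.init, str):
            inits = [
                X[rng.choice(N, self.n_clusters, replace=False)].copy()
                for _ in range(self.n_init)
            ]
        else:
            C0 = np.asarray(self.init, dtype=float)
            if C0.shape != (self.n_clusters, X.shape[1]):
                raise ValueError("init centroids have wrong shape")
            inits = [C0.copy()]
        best = None
        for C0 in inits:
            centers, labels, inertia, history = self._lloyd(X, C0)
            if best is None or inertia < best[2]:
                best = (centers, labels, inertia, history)
        self.cluster_centers_, self.labels_, self.inertia_, self.inertia_history_ = best
        self.n_iter_ = len(self.inertia_history_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        D = cdist(np.asarray(X, dtype=float), self.cluster_centers_, "cityblock")
        return np.argmin(D, axis=1)


@dataclass
class StatePartition:
    """A k-state decomposition of pooled windowed FC.

    ``assignments`` maps subject id to its length-Nw vector of 1-based
    state labels; ``centroids`` is k×P in Fisher-z units.
    """

    k: int
    centroids: np.ndarray
    assignments: dict[str, np.ndarray]
    inertia: float
    inertia_history: list[float] = field(default_factory=list)
    config_fingerprint: str = ""

    def pooled_labels(self, order: Sequence[str] | None = None) -> np.ndarray:
        sids = list(order) if order is not None else list(self.assignments)
        return np.concatenate([self.assignments[s] for s in sids])


@dataclass
class ClusterValidity:
    """Model-order diagnostics per candidate k (all distances L1)."""

    k_values: list[int]
    silhouette: list[float]
    wcss: list[float]
    dunn: list[float]


def _fingerprint(**kwargs) -> str:
    blob = repr(sorted(kwargs.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def kmeans_l1(
    X: np.ndarray,
    k: int,
    init_centroids: np.ndarray | None = None,
    max_iter: int = 500,
    n_init: int = 10,
    seed: int | None = 0,
) -> L1KMeans:
    """Functional wrapper over :class:`L1KMeans`; returns the fitted estimator."""
    est = L1KMeans(
        n_clusters=k,
        init="random" if init_centroids is None else init_centroids,
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
    )
    return est.fit(np.asarray(X, dtype=float))


def exemplar_windows(z_matrix: np.ndarray) -> np.ndarray:
    """Indices of windows at local maxima of across-pair FC variance.

    Endpoints count when they exceed their single neighbour.  Falls back
    to the single global maximum for very short series.
    """
    v = z_matrix.var(axis=1)
    n = v.shape[0]
    if n < 3:
        return np.array([int(np.argmax(v))])
    idx = [i for i in range(1, n - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]]
    if v[0] > v[1]:
        idx.insert(0, 0)
    if v[-1] > v[-2]:
        idx.append(n - 1)
    if not idx:
        idx = [int(np.argmax(v))]
    return np.asarray(sorted(idx))


def two_stage_cluster(
    cohort_fc: Sequence[WindowedFCSeries],
    k: int,
    exemplar_mode: str = "variance_peaks",
    n_init: int = 10,
    max_iter: int = 500,
    seed: int = 0,
) -> StatePartition:
    """Two-stage L1 k-means over the pooled cohort windows.

    Stage 1 clusters exemplar windows (per-subject variance peaks, or all
    windows when ``exemplar_mode="all"``) with ``n_init`` restarts; stage
    2 runs a single full-data pass initialised at the stage-1 centroids.
    """
    if not cohort_fc:
        raise ValueError("empty cohort")
    if exemplar_mode not in ("variance_peaks", "all"):
        raise ValueError("exemplar_mode must be variance_peaks|all")
    pooled = np.vstack([fc.z_matrix for fc in cohort_fc])
    if exemplar_mode == "variance_peaks":
        ex = np.vstack(
            [fc.z_matrix[exemplar_windows(fc.z_matrix)] for fc in cohort_fc]
        )
        if ex.shape[0] < k:
            logger.warning(
                "only %d exemplars for k=%d; falling back to all windows",
                ex.shape[0], k,
            )
            ex = pooled
    else:
        ex = pooled
    stage1 = kmeans_l1(ex, k, max_iter=max_iter, n_init=n_init, seed=seed)
    stage2 = kmeans_l1(
        pooled, k, init_centroids=stage1.cluster_centers_, max_iter=max_iter
    )
    labels = stage2.labels_ + 1  # 1-based state labels
    assignments: dict[str, np.ndarray] = {}
    off = 0
    for fc in cohort_fc:
        assignments[fc.subject_id] = labels[off : off + fc.n_windows]
        off += fc.n_windows
    return StatePartition(
        k=k,
        centroids=stage2.cluster_centers_,
        assignments=assignments,
        inertia=stage2.inertia_,
        inertia_history=stage2.inertia_history_,
        config_fingerprint=_fingerprint(
            k=k, exemplar_mode=exemplar_mode, n_init=n_init,
            max_iter=max_iter, seed=seed,
        ),
    )


def _dunn_index(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Dunn = min inter-centroid L1 distance / max intra-cluster L1 diameter."""
    k = centers.shape[0]
    inter = np.inf
    for i in range(k):
        for j in range(i + 1, k):
            inter = min(inter, float(np.abs(centers[i] - centers[j]).sum()))
    diam = 0.0
    for j in range(k):
        pts = X[labels == j]
        if pts.shape[0] > 1:
            diam = max(diam, float(cdist(pts, pts, "cityblock").max()))
    if diam == 0.0:
        return np.inf
    return inter / diam


def cluster_validity(
    X: np.ndarray,
    k_values: Sequence[int],
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
    sample_size: int | None = 4000,
) -> ClusterValidity:
    """Silhouette / WCSS (elbow) / Dunn per candidate k, L1 throughout.

    The quadratic-cost silhouette and Dunn diagnostics are evaluated on a
    seeded subsample when N exceeds ``sample_size``.  Singleton clusters
    leave their point's silhouette undefined; such points are excluded
    from the mean with a logged count.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if max(k_values) > N:
        raise ValueError("max k exceeds the number of points")
    rng = np.random.default_rng(seed)
    if sample_size is not None and N > sample_size:
        sub = rng.choice(N, sample_size, replace=False)
    else:
        sub = np.arange(N)
    sil, wcss, dunn = [], [], []
    for k in k_values:
        est = kmeans_l1(X, k, max_iter=max_iter, n_init=n_init, seed=seed)
        wcss.append(est.inertia_)
        labels_sub = est.labels_[sub]
        if k == 1 or len(np.unique(labels_sub)) < 2:
            sil.append(float("nan"))
            dunn.append(float("nan"))
            continue
        s = silhouette_samples(X[sub], labels_sub, metric="manhattan")
        counts = np.bincount(labels_sub, minlength=k)
        singleton = counts[labels_sub] == 1
        if singleton.any():
            logger.info(
                "silhouette: excluded %d singleton-cluster points",
                int(singleton.sum()),
            )
        sil.append(float(s[~singleton].mean()))
        dunn.append(_dunn_index(X[sub], labels_sub, est.cluster_centers_))
    return ClusterValidity(list(k_values), sil, wcss, dunn)


def match_centroids(
    A: np.ndarray, B: np.ndarray, method: str = "greedy"
) -> tuple[list[tuple[int, int]], list[float]]:
    """One-to-one centroid matching by maximal Pearson correlation.

    Returns the matched index pairs (row of A, row of B) and their
    correlations.  ``method`` is ``"greedy"`` or ``"hungarian"``.
    """
    k = A.shape[0]
    corr = np.corrcoef(A, B)[:k, k:]
    if method == "hungarian":
        from scipy.optimize import linear_sum_assignment

        ri, ci = linear_sum_assignment(-corr)
        pairs = list(zip(ri.tolist(), ci.tolist()))
    elif method == "greedy":
        pairs = []
        used_a, used_b = set(), set()
        order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
        for i, j in order:
            if i not in used_a and j not in used_b:
                pairs.append((int(i), int(j)))
                used_a.add(int(i))
                used_b.add(int(j))
    else:
        raise ValueError("method must be greedy|hungarian")
    pairs.sort()
    return pairs, [float(corr[i, j]) for i, j in pairs]


def split_half_reproducibility(
    cohort_fc: Sequence[WindowedFCSeries],
    k: int,
    n_random_sets: int = 5,
    exemplar_mode: str = "variance_peaks",
    n_init: int = 10,
    seed: int = 0,
) -> dict:
    """Centroid reproducibility across subject resamples.

    Clusters two non-overlapping split halves (matched against each
    other) and ``n_random_sets`` random half-size subject subsets
    (each matched against the full-cohort centroids).  Matching is
    greedy maximal Pearson correlation.
    """
    n = len(cohort_fc)
    if n < 2 * k:
        raise ValueError("need at least 2k subjects for a split-half check")
    rng = np.random.default_rng(seed)

    def _cluster(subset):
        return two_stage_cluster(
            subset, k, exemplar_mode=exemplar_mode, n_init=n_init,
            seed=int(rng.integers(2**31 - 1)),
        ).centroids

    full_centroids = _cluster(list(cohort_fc))
    perm = rng.permutation(n)
    half_a = [cohort_fc[i] for i in perm[: n // 2]]
    half_b = [cohort_fc[i] for i in perm[n // 2 :]]
    _, split_corr = match_centroids(_cluster(half_a), _cluster(half_b))
    random_sets = []
    for _ in range(n_random_sets):
        pick = rng.choice(n, n // 2, replace=False)
        cents = _cluster([cohort_fc[i] for i in pick])
        _, corrs = match_centroids(full_centroids, cents)
        random_sets.append(corrs)
    return {
        "split_half": split_corr,
        "random_sets": random_sets,
        "n_random_sets": n_random_sets,
        "seed": seed,
    }


def group_state_medians(
    partition: StatePartition,
    cohort_fc: Sequence[WindowedFCSeries],
    groups: dict[str, str] | None = None,
) -> dict[tuple[str, int], np.ndarray]:
    """Elementwise median Fisher-z vector per (group, state).

    ``groups`` maps subject id to group label; defaults to each series'
    own ``group`` field.  A (group, state) cell with no windows is
    reported as missing (all-NaN) with a warning.
    """
    groups = groups or {fc.subject_id: fc.group for fc in cohort_fc}
    by_cell: dict[tuple[str, int], list[np.ndarray]] = {}
    P = cohort_fc[0].z_matrix.shape[1]
    for fc in cohort_fc:
        g = groups[fc.subject_id]
        lab = partition.assignments[fc.subject_id]
        for s in range(1, partition.k + 1):
            rows = fc.z_matrix[lab == s]
            if rows.size:
                by_cell.setdefault((g, s), []).append(rows)
    out: dict[tuple[str, int], np.ndarray] = {}
    for g in sorted(set(groups.values())):
        for s in range(1, partition.k + 1):
            cell = by_cell.get((g, s))
            if cell is None:
                warnings.warn(f"group {g} has no windows in state {s}")
                out[(g, s)] = np.full(P, np.nan)
            else:
                out[(g, s)] = np.median(np.vstack(cell), axis=0)
    return out
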