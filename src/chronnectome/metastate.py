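"""Meta-state dynamics: continuous pattern loadings, quartile
discretization, and the four meta-state metrics.

Each window's Fisher-z connectivity vector is decomposed onto the k
connectivity patterns (the k-means state centroids) as continuous
loadings — by default the Pearson correlation between the window vector
and each centroid.  Loadings are then discretized to the eight levels
±{1,2,3,4}: per pattern dimension, the 25/50/75 percentiles of the
|loading| distribution over the reference windows (that subject's
windows by default) define the magnitude quartile, and the original sign
is reattached.  A *meta-state* is one discretized k-vector; the four
summary metrics are the number of distinct meta-states, the number of
meta-state changes, the span (maximum pairwise L1 distance among
occupied meta-states) and the total distance travelled (sum of L1
distances between successive meta-states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .windows import WindowedFCSeries

__all__ = [
    "MetaStateResult",
    "metastate_loadings",
    "quartile_discretize",
    "metastate_metrics",
    "metastate_result",
    "MetaStateDiscretizer",
]


@dataclass
class MetaStateResult:
    subject_id: str
    loadings: np.ndarray  # Nw x k, continuous
    discrete: np.ndarray  # Nw x k, entries in ±{1,2,3,4}
    n_meta_states: int
    n_changes: int
    span: float
    total_distance: float
    group: str = ""


def metastate_loadings(
    fc: WindowedFCSeries | np.ndarray,
    centroids: np.ndarray,
    kind: str = "correlation",
) -> np.ndarray:
    """Continuous loadings of each window on each connectivity pattern.

    ``kind="correlation"`` (default): Pearson correlation between the
    window's z-vector and each centroid.  ``kind="regression"``: least
    squares weights of the window vector on the centroid basis.
    """
    Z = fc.z_matrix if isinstance(fc, WindowedFCSeries) else np.asarray(fc)
    C = np.asarray(centroids, dtype=float)
    if Z.shape[1] != C.shape[1]:
        raise ValueError("pair dimension mismatch between windows and centroids")
    if kind == "regression":
        coef, *_ = np.linalg.lstsq(C.T, Z.T, rcond=None)
        return coef.T
    if kind != "correlation":
        raise ValueError("kind must be correlation|regression")
    Zc = Z - Z.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    zn = np.linalg.norm(Zc, axis=1)
    cn = np.linalg.norm(Cc, axis=1)
    bad = np.flatnonzero(zn == 0)
    if bad.size:
        raise ValueError(f"zero-variance window vector at window {bad[0]}")
    if np.any(cn == 0):
        raise ValueError("zero-variance centroid")
    return (Zc @ Cc.T) / np.outer(zn, cn)


def quartile_discretize(
    loadings: np.ndarray,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Map continuous loadings to the eight levels ±{1,2,3,4}.

    Per pattern dimension j, the 25/50/75 percentiles (linear
    interpolation) of |loading| over the reference windows (``reference``
    defaults to ``loadings`` itself — the per-subject convention) split
    the magnitudes into quartile bins; each weight maps to
    ``sign(weight) × (1 + number of percentiles strictly below
    |weight|)``, so boundary values fall in the lower bin.  Zero weights
    take the + sign.  A constant-magnitude reference column maps
    everything to level 1 with a warning.
    """
    L = np.asarray(loadings, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("loadings must be finite")
    ref = L if reference is None else np.asarray(reference, dtype=float)
    if ref.shape[1] != L.shape[1]:
        raise ValueError("reference must share the pattern dimension")
    out = np.empty(L.shape, dtype=int)
    for j in range(L.shape[1]):
        q = np.percentile(np.abs(ref[:, j]), [25, 50, 75])
        if q[0] == q[2]:
            import warnings

            warnings.warn(f"constant |loading| column {j}; all map to level 1")
        mag = 1 + np.searchsorted(q, np.abs(L[:, j]), side="left")
        sign = np.where(L[:, j] < 0, -1, 1)  # zero weights take +
        out[:, j] = sign * mag
    return out


def metastate_metrics(discrete: np.ndarray) -> tuple[int, int, float, float]:
    """(n_meta_states, n_changes, span, total_distance) of a trajectory.

    All distances are L1 over the k-vector of discrete levels; span is
    over the set of distinct occupied meta-states, total distance over
    successive windows.
    """
    D = np.asarray(discrete, dtype=int)
    if D.ndim != 2 or D.size == 0:
        raise ValueError("discrete trajectory must be a non-empty Nw x k matrix")
    levels = np.abs(D)
    if levels.min() < 1 or levels.max() > 4:
        raise ValueError("discrete entries must lie in ±{1,2,3,4}")
    uniq = np.unique(D, axis=0)
    n_meta_states = uniq.shape[0]
    step_diff = np.abs(np.diff(D, axis=0)).sum(axis=1)
    n_changes = int(np.count_nonzero(step_diff))
    total_distance = float(step_diff.sum())
    span = float(pdist(uniq, "cityblock").max()) if n_meta_states > 1 else 0.0
    return n_meta_states, n_changes, span, total_distance


def metastate_result(
    fc: WindowedFCSeries,
    centroids: np.ndarray,
    reference: str = "subject",
    cohort_loadings: np.ndarray | None = None,
    loading_kind: str = "correlation",
) -> MetaStateResult:
    """Full meta-state computation for one subject.

    ``reference="cohort"`` requires ``cohort_loadings`` (pooled Nw_total×k
    loadings) for the quartile percentiles; the default is the subject's
    own windows.
    """
    load = metastate_loadings(fc, centroids, kind=loading_kind)
    if reference == "subject":
        ref = None
    elif reference == "cohort":
        if cohort_loadings is None:
            raise ValueError("cohort reference requires cohort_loadings")
        ref = cohort_loadings
    else:
        raise ValueError("reference must be subject|cohort")
    disc = quartile_discretize(load, reference=ref)
    n_ms, n_ch, span, total = metastate_metrics(disc)
    return MetaStateResult(
        subject_id=fc.subject_id,
        loadings=load,
        discrete=disc,
        n_meta_states=n_ms,
        n_changes=n_ch,
        span=span,
        total_distance=total,
        group=fc.group,
    )


class MetaStateDiscretizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: windowed FC vectors → discrete meta-states.

    ``fit`` stores the connectivity-pattern centroids (and, for the
    cohort reference, the pooled loading percentile basis); ``transform``
    maps an Nw×P window matrix to its Nw×k discrete ±{1..4} trajectory.
    """

    def __init__(
        self,
        centroids: np.ndarray | None = None,
        reference: str = "subject",
        loading_kind: str = "correlation",
    ):
        self.centroids = centroids
        self.reference = reference
        self.loading_kind = loading_kind

    def fit(self, X: np.ndarray, y=None) -> "MetaStateDiscretizer":
        if self.centroids is None:
            raise ValueError("centroids must be provided")
        self.centroids_ = np.asarray(self.centroids, dtype=float)
        if self.reference == "cohort":
            self.reference_loadings_ = metastate_loadings(
                np.asarray(X, dtype=float), self.centroids_, self.loading_kind
            )
        self.n_features_in_ = self.centroids_.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        load = metastate_loadings(
            np.asarray(X, dtype=float), self.centroids_, self.loading_kind
        )
        ref = (
            self.reference_loadings_ if self.reference == "cohort" else None
        )
        return quartile_discretize(load, reference=ref)
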