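"""Group statistics for dynamics metrics and state connectivity.

Covers the inferential machinery of a three-group dynamics comparison:
a one-way general linear model (optionally with nuisance covariates)
with Fisher's LSD post-hoc pairwise tests and Cohen's d effect sizes;
two-sample Hotelling's T² (and a MANOVA omnibus) on state-occupancy
profiles; threshold-free network-based statistics (TFNBS) for edgewise
group differences in state connectivity with max-statistic permutation
FWE control; Spearman rank correlations against questionnaire scores;
and a 1.5·IQR outlier screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GroupComparison",
    "EdgeStatsReport",
    "oneway_glm",
    "lsd_posthoc",
    "cohens_d",
    "group_comparison",
    "hotelling_t2",
    "hotelling_omnibus",
    "tfnbs",
    "spearman",
    "outlier_screen",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """Omnibus GLM + LSD post-hocs + Cohen's d for one scalar metric."""

    metric_name: str
    omnibus_F: float
    omnibus_p: float
    df: tuple[float, float]
    pairwise: dict[tuple[str, str], dict[str, float]]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]


@dataclass
class EdgeStatsReport:
    """TFNBS result for one state and group pair."""

    state: int
    group_pair: tuple[str, str]
    edge_t: np.ndarray
    tfnbs_score: np.ndarray
    fwe_p: np.ndarray
    n_permutations: int
    seed: int
    params: dict = field(default_factory=dict)


def _drop_missing(values, groups, covariates=None):
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if covariates is not None:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != v.shape[0]:
            X = X.T
        ok = np.isfinite(v) & np.all(np.isfinite(X), axis=1)
    else:
        X = None
        ok = np.isfinite(v)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d subjects with missing values", dropped)
    return v[ok], g[ok], (X[ok] if X is not None else None)


def oneway_glm(values, groups, covariates=None):
    """One-way fixed-effects GLM F-test for the group factor.

    Covariates enter as nuisance columns; the F statistic compares the
    full model (intercept + covariates + group dummies) with the reduced
    model (intercept + covariates).  Returns ``(F, p, df_resid)``.
    """
    import statsmodels.api as sm

    v, g, X = _drop_missing(values, groups, covariates)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 usable values each")
    dummies = pd.get_dummies(pd.Series(g), drop_first=True).to_numpy(float)
    base = np.ones((v.shape[0], 1))
    if X is not None:
        base = np.hstack([base, X])
    full = sm.OLS(v, np.hstack([base, dummies])).fit()
    reduced = sm.OLS(v, base).fit()
    if reduced.ssr < 1e-12 or reduced.ssr - full.ssr <= 0:
        return 0.0, 1.0, float(full.df_resid)  # degenerate: no group variance
    F, p, _ = full.compare_f_test(reduced)
    return float(F), float(p), float(full.df_resid)


def lsd_posthoc(values, groups, covariates=None):
    """Fisher's LSD pairwise p-values from the pooled omnibus error term.

    Each pair is tested with t = (mean_i - mean_j) / sqrt(MSE (1/n_i +
    1/n_j)) on the omnibus residual df; by the LSD definition no
    multiplicity adjustment is applied.  Returns {(a, b): p}.
    """
    v, g, X = _drop_missing(values, groups, covariates)
    labels = sorted(np.unique(g).tolist())
    n = v.shape[0]
    if X is not None:
        # residualise on covariates before pooling the error term
        import statsmodels.api as sm

        base = np.hstack([np.ones((n, 1)), X])
        dummies = pd.get_dummies(pd.Series(g), drop_first=True).to_numpy(float)
        full = sm.OLS(v, np.hstack([base, dummies])).fit()
        mse, df_resid = full.mse_resid, full.df_resid
    else:
        ss_within = sum(
            ((v[g == lab] - v[g == lab].mean()) ** 2).sum() for lab in labels
        )
        df_resid = n - len(labels)
        mse = ss_within / df_resid
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            va, vb = v[g == a], v[g == b]
            se = np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
            if se == 0:
                out[(a, b)] = 1.0
                continue
            t = (va.mean() - vb.mean()) / se
            out[(a, b)] = float(2 * stats.t.sf(abs(t), df_resid))
    return out


def cohens_d(a, b) -> float:
    """(mean(a) - mean(b)) / pooled SD with (n-1)-weighted pooling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled SD; d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def group_comparison(metric_name, values, groups, covariates=None) -> GroupComparison:
    """Omnibus F + LSD post-hocs + Cohen's d for one scalar metric.

    Post-hocs are reported regardless of the omnibus p-value.
    """
    v, g, _ = _drop_missing(values, groups, covariates)
    F, p, df_resid = oneway_glm(values, groups, covariates)
    lsd = lsd_posthoc(values, groups, covariates)
    labels = sorted(np.unique(g).tolist())
    pairwise = {}
    for (a, b), pv in lsd.items():
        va, vb = v[g == a], v[g == b]
        try:
            d = cohens_d(va, vb)
        except ValueError:
            d = float("nan")
        pairwise[(a, b)] = {"lsd_p": pv, "cohens_d": d}
    return GroupComparison(
        metric_name=metric_name,
        omnibus_F=F,
        omnibus_p=p,
        df=(len(labels) - 1, df_resid),
        pairwise=pairwise,
        group_means={lab: float(v[g == lab].mean()) for lab in labels},
        group_sds={lab: float(v[g == lab].std(ddof=1)) for lab in labels},
        group_ns={lab: int((g == lab).sum()) for lab in labels},
    )


def hotelling_t2(A, B, drop_last: bool | None = None):
    """Two-sample Hotelling's T² with pooled covariance.

    ``drop_last=None`` auto-drops the final column when rows are
    compositional (sum to 1), removing the occupancy-profile redundancy.
    Returns ``(T2, F, p)``; F uses the standard conversion with
    ``(p, nA + nB - p - 1)`` degrees of freedom.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    if drop_last is None:
        drop_last = A.shape[1] > 1 and np.allclose(
            A.sum(axis=1), 1.0, atol=1e-9
        ) and np.allclose(B.sum(axis=1), 1.0, atol=1e-9)
    if drop_last:
        A, B = A[:, :-1], B[:, :-1]
    nA, p = A.shape
    nB = B.shape[0]
    if nA + nB - 2 <= p:
        raise ValueError("too few subjects for the retained dimensions")
    diff = A.mean(axis=0) - B.mean(axis=0)
    Sp = ((nA - 1) * np.cov(A, rowvar=False, ddof=1)
          + (nB - 1) * np.cov(B, rowvar=False, ddof=1)) / (nA + nB - 2)
    Sp = np.atleast_2d(Sp)
    try:
        sol = np.linalg.solve(Sp, diff)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular pooled covariance; drop a redundant dimension"
        ) from err
    T2 = float(nA * nB / (nA + nB) * diff @ sol)
    F = T2 * (nA + nB - p - 1) / (p * (nA + nB - 2))
    pval = float(stats.f.sf(F, p, nA + nB - p - 1))
    return T2, float(F), pval


def hotelling_omnibus(groups_data: dict[str, np.ndarray], drop_last: bool | None = None):
    """MANOVA-style omnibus across >= 2 groups (Wilks' lambda F).

    ``groups_data`` maps group label to its n×k occupancy matrix.
    Returns ``(wilks_lambda, F, p)``.
    """
    from statsmodels.multivariate.manova import MANOVA

    mats = list(groups_data.values())
    if drop_last is None:
        drop_last = mats[0].shape[1] > 1 and all(
            np.allclose(m.sum(axis=1), 1.0, atol=1e-9) for m in mats
        )
    if drop_last:
        mats = [m[:, :-1] for m in mats]
    endog = np.vstack(mats)
    labels = np.concatenate(
        [[lab] * m.shape[0] for lab, m in zip(groups_data, mats)]
    )
    if endog.shape[1] == 1:
        # univariate: the omnibus reduces to one-way ANOVA; Wilks' lambda
        # is SSE/(SSH+SSE) = 1/(1 + F df1/df2)
        F, p, df2 = oneway_glm(endog[:, 0], labels)
        df1 = len(groups_data) - 1
        return float(1.0 / (1.0 + F * df1 / df2)), F, p
    exog = pd.get_dummies(pd.Series(labels), drop_first=True).to_numpy(float)
    exog = np.hstack([np.ones((endog.shape[0], 1)), exog])
    mv = MANOVA(endog, exog)
    # hypothesis: all group-dummy coefficients zero
    L = np.hstack([np.zeros((exog.shape[1] - 1, 1)), np.eye(exog.shape[1] - 1)])
    res = mv.mv_test(hypotheses=[("group", L)])
    tbl = res.results["group"]["stat"]
    row = tbl.loc["Wilks' lambda"]
    return float(row["Value"]), float(row["F Value"]), float(row["Pr > F"])


# ------------------------------ TFNBS --------------------------------------


def _edgewise_t(XA: np.ndarray, XB: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per edge (vectorised)."""
    nA, nB = XA.shape[0], XB.shape[0]
    mA, mB = XA.mean(axis=0), XB.mean(axis=0)
    vA = XA.var(axis=0, ddof=1)
    vB = XB.var(axis=0, ddof=1)
    sp2 = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
    se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mA - mB) / se, 0.0)
    return t


def _enhance(t: np.ndarray, ei: np.ndarray, ej: np.ndarray, n_nodes: int,
             E: float, H: float, dh: float, thresholds: np.ndarray) -> np.ndarray:
    """TFNBS enhancement of one signed direction (positive t only)."""
    score = np.zeros_like(t)
    for h in thresholds:
        mask = t > h
        if not mask.any():
            break  # thresholds ascend; nothing survives higher ones
        A = sparse.coo_matrix(
            (np.ones(mask.sum()), (ei[mask], ej[mask])),
            shape=(n_nodes, n_nodes),
        )
        _, comp = connected_components(A, directed=False)
        edge_comp = comp[ei[mask]]
        comp_edges = np.bincount(edge_comp, minlength=n_nodes)
        score[mask] += comp_edges[edge_comp] ** E * h**H * dh
    return score


def tfnbs(
    group_a: np.ndarray,
    group_b: np.ndarray,
    pair_index: list[tuple[int, int]],
    n_nodes: int,
    n_permutations: int = 5000,
    E: float = 0.5,
    H: float = 3.0,
    dh: float | None = None,
    seed: int = 0,
    state: int = 0,
    group_pair: tuple[str, str] = ("A", "B"),
) -> EdgeStatsReport:
    """Threshold-free network-based statistics for one group pair.

    ``group_a``/``group_b`` are per-subject P-vectors (e.g. each
    subject's mean Fisher-z vector over their windows in one state).
    Edgewise pooled-t statistics are enhanced over an ascending threshold
    ladder: each suprathreshold edge accrues
    ``(component size in edges)^E × h^H × dh`` where components are taken
    on the C-node graph of suprathreshold edges.  Both signed directions
    are enhanced separately and summed per edge; family-wise error is
    controlled by the permutation distribution of the maximum enhanced
    score under group-label shuffling.
    """
    XA = np.atleast_2d(np.asarray(group_a, dtype=float))
    XB = np.atleast_2d(np.asarray(group_b, dtype=float))
    if XA.shape[0] < 2 or XB.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if n_permutations < 100:
        import warnings

        warnings.warn("fewer than 100 permutations; p-values are coarse")
    P = XA.shape[1]
    ei = np.array([i - 1 for i, _ in pair_index])
    ej = np.array([j - 1 for _, j in pair_index])
    if ei.shape[0] != P:
        raise ValueError("pair_index length must match the edge dimension")

    t_obs = _edgewise_t(XA, XB)
    max_t = np.abs(t_obs).max()
    if max_t == 0:
        zeros = np.zeros(P)
        return EdgeStatsReport(state, group_pair, t_obs, zeros,
                               np.ones(P), n_permutations, seed)
    dh_val = float(dh) if dh is not None else max_t / 100.0
    thresholds = np.arange(dh_val, max_t + dh_val / 2, dh_val)

    def _score(t):
        return (_enhance(t, ei, ej, n_nodes, E, H, dh_val, thresholds)
                + _enhance(-t, ei, ej, n_nodes, E, H, dh_val, thresholds))

    obs = _score(t_obs)
    pooled = np.vstack([XA, XB])
    nA = XA.shape[0]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(P)
    for _ in range(n_permutations):
        perm = rng.permutation(pooled.shape[0])
        tp = _edgewise_t(pooled[perm[:nA]], pooled[perm[nA:]])
        exceed += _score(tp).max() >= obs
    fwe_p = (1.0 + exceed) / (n_permutations + 1.0)
    return EdgeStatsReport(
        state=state,
        group_pair=group_pair,
        edge_t=t_obs,
        tfnbs_score=obs,
        fwe_p=fwe_p,
        n_permutations=n_permutations,
        seed=seed,
        params={"E": E, "H": H, "dh": dh_val},
    )


def spearman(x, y):
    """Spearman rank correlation with midrank ties; p via the t approximation.

    Incomplete pairs are dropped pairwise; needs >= 4 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def outlier_screen(values, rule: str = "iqr_1p5") -> np.ndarray:
    """Indices retained after the 1.5·IQR fence screen (``rule="none"`` keeps all)."""
    v = np.asarray(values, dtype=float)
    if rule == "none":
        return np.arange(v.size)
    if rule != "iqr_1p5":
        raise ValueError("rule must be iqr_1p5|none")
    if v.size < 5:
        raise ValueError("need >= 5 values for the IQR rule")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = np.flatnonzero((v >= lo) & (v <= hi))
    flagged = np.setdiff1d(np.arange(v.size), keep)
    if flagged.size:
        logger.info("outlier screen flagged indices %s", flagged.tolist())
    return keep
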