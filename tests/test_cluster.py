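import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from chronnectome import (
    cluster_validity,
    group_state_medians,
    kmeans_l1,
    match_centroids,
    split_half_reproducibility,
    two_stage_cluster,
)
from chronnectome.cluster import L1KMeans, exemplar_windows
from chronnectome.windows import WindowedFCSeries, pair_index


def brute_force_l1_partition(x: np.ndarray, k: int):
    """Exhaustive minimum total-L1 partition of a small 1-D sample."""
    n = x.shape[0]
    best_cost, best_labels = np.inf, None
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        cost = 0.0
        for j in range(k):
            pts = x[labels == j]
            if pts.size:
                cost += np.abs(pts - np.median(pts)).sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_cost, best_labels


class TestKmeansL1:
    def test_two_well_separated_1d_clusters(self):
        X = np.array([0.0, 0.0, 1.0, 10.0, 10.0, 11.0]).reshape(-1, 1)
        est = kmeans_l1(X, 2, n_init=10, seed=0)
        cents = np.sort(est.cluster_centers_.ravel())
        assert np.allclose(cents, [0.0, 10.0])
        assert adjusted_rand_score(est.labels_, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_k1_centroid_is_coordinate_median(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((21, 4))
        est = kmeans_l1(X, 1, seed=0)
        assert np.allclose(est.cluster_centers_[0], np.median(X, axis=0))

    def test_planted_high_dimensional_clusters_recovered(self):
        rng = np.random.default_rng(1)
        P = 435
        mu = rng.standard_normal(P) * 10  # ~10 sigma separation
        X = np.vstack([
            rng.standard_normal((40, P)),
            mu + rng.standard_normal((40, P)),
        ])
        truth = np.repeat([0, 1], 40)
        est = kmeans_l1(X, 2, n_init=5, seed=2)
        assert adjusted_rand_score(est.labels_, truth) == 1.0

    def test_centroids_are_medians_at_convergence(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 5))
        est = kmeans_l1(X, 3, n_init=3, seed=4)
        for j in range(3):
            assert np.allclose(
                est.cluster_centers_[j], np.median(X[est.labels_ == j], axis=0),
                atol=1e-9,
            )

    def test_inertia_non_increasing_over_iterations(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 8))
        est = kmeans_l1(X, 4, n_init=5, seed=6)
        h = est.inertia_history_
        assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_l1(np.zeros((2, 2)), 3)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 6))
        a = kmeans_l1(X, 3, seed=11)
        b = kmeans_l1(X, 3, seed=11)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.allclose(a.cluster_centers_, b.cluster_centers_)

    def test_sklearn_predict_matches_labels(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 3))
        est = L1KMeans(n_clusters=2, random_state=0).fit(X)
        assert np.array_equal(est.predict(X), est.labels_)


def _fc_from_matrix(sid, group, Z):
    return WindowedFCSeries(
        subject_id=sid, group=group,
        pair_index=pair_index(int((1 + np.sqrt(1 + 8 * Z.shape[1])) / 2)),
        z_matrix=Z, lambda_used=0.1,
    )


@pytest.fixture(scope="module")
def planted_fc_cohort():
    """10 subjects whose windows alternate between two planted FC patterns."""
    rng = np.random.default_rng(9)
    P = 45  # C = 10
    c1 = rng.standard_normal(P)
    c2 = c1 + rng.standard_normal(P) * 4
    cohort = []
    truth = []
    for i in range(10):
        labels = rng.integers(0, 2, size=60)
        Z = np.where(labels[:, None] == 0, c1, c2) + 0.3 * rng.standard_normal(
            (60, P)
        )
        cohort.append(_fc_from_matrix(f"s{i}", "A" if i < 5 else "B", Z))
        truth.append(labels)
    return cohort, np.concatenate(truth), np.vstack([c1, c2])


class TestTwoStage:
    def test_pooled_instance_count(self, planted_fc_cohort):
        cohort, truth, _ = planted_fc_cohort
        part = two_stage_cluster(cohort, 2, seed=0)
        assert sum(len(v) for v in part.assignments.values()) == 600

    def test_degenerate_two_stage_equals_single_stage(self, planted_fc_cohort):
        cohort, _, _ = planted_fc_cohort
        pooled = np.vstack([fc.z_matrix for fc in cohort])
        part = two_stage_cluster(cohort, 2, exemplar_mode="all", n_init=1,
                                 seed=3)
        single = kmeans_l1(pooled, 2, n_init=1, seed=3)
        assert np.allclose(part.centroids, single.cluster_centers_)
        assert np.array_equal(part.pooled_labels(
            [fc.subject_id for fc in cohort]) - 1, single.labels_)

    def test_planted_centroids_recovered(self, planted_fc_cohort):
        cohort, truth, C = planted_fc_cohort
        part = two_stage_cluster(cohort, 2, seed=1)
        _, corrs = match_centroids(part.centroids, C)
        assert min(corrs) > 0.95
        acc = max(
            (part.pooled_labels([fc.subject_id for fc in cohort]) - 1 == truth).mean(),
            (2 - part.pooled_labels([fc.subject_id for fc in cohort]) == truth).mean(),
        )
        assert acc >= 0.95

    def test_exemplars_are_variance_peaks(self):
        Z = np.zeros((6, 3))
        Z[2] = (0, 5, -5)  # interior variance spike
        idx = exemplar_windows(Z)
        assert 2 in idx


class TestValidity:
    def test_separated_clusters_have_high_silhouette(self):
        rng = np.random.default_rng(10)
        X = np.vstack([
            rng.standard_normal((50, 10)),
            20 + rng.standard_normal((50, 10)),
        ])
        v = cluster_validity(X, [2], seed=0, n_init=3)
        assert v.silhouette[0] > 0.9

    def test_single_blob_has_low_silhouette(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((120, 10))
        v = cluster_validity(X, [2], seed=0, n_init=3)
        assert v.silhouette[0] < 0.3

    def test_wcss_non_increasing_in_k(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((100, 6))
        v = cluster_validity(X, [2, 4], seed=0, n_init=10)
        assert v.wcss[1] <= v.wcss[0] + 1e-9

    def test_dunn_higher_for_separated_data(self):
        rng = np.random.default_rng(13)
        sep = np.vstack([rng.standard_normal((40, 5)),
                         30 + rng.standard_normal((40, 5))])
        blob = rng.standard_normal((80, 5))
        d_sep = cluster_validity(sep, [2], seed=0, n_init=3).dunn[0]
        d_blob = cluster_validity(blob, [2], seed=0, n_init=3).dunn[0]
        assert d_sep > d_blob


class TestSplitHalf:
    def test_identical_halves_match_perfectly(self, planted_fc_cohort):
        cohort, _, _ = planted_fc_cohort
        doubled = cohort + cohort
        rep = split_half_reproducibility(doubled, 2, n_random_sets=1, seed=0)
        assert min(rep["split_half"]) > 0.99

    def test_planted_states_reproduce_across_subsets(self, planted_fc_cohort):
        cohort, _, _ = planted_fc_cohort
        rep = split_half_reproducibility(cohort, 2, n_random_sets=5, seed=1)
        assert len(rep["random_sets"]) == 5
        assert min(rep["split_half"]) > 0.9
        assert all(min(r) > 0.9 for r in rep["random_sets"])


class TestGroupStateMedians:
    def test_median_is_robust_to_outliers(self, planted_fc_cohort):
        cohort, _, _ = planted_fc_cohort
        part = two_stage_cluster(cohort, 2, seed=2)
        meds = group_state_medians(part, cohort)
        # brute-force oracle: independent sort-based median per cell
        fc0 = cohort[0]
        g = fc0.group
        pooled = []
        for fc in cohort:
            if fc.group == g:
                lab = part.assignments[fc.subject_id]
                pooled.append(fc.z_matrix[lab == 1])
        oracle = np.sort(np.vstack(pooled), axis=0)
        n = oracle.shape[0]
        exact = (oracle[(n - 1) // 2] + oracle[n // 2]) / 2.0
        assert np.array_equal(meds[(g, 1)], exact)

    def test_missing_cell_reported_as_nan(self, planted_fc_cohort):
        cohort, _, _ = planted_fc_cohort
        part = two_stage_cluster(cohort, 2, seed=2)
        # force group A entirely into state 1
        for fc in cohort:
            if fc.group == "A":
                part.assignments[fc.subject_id][:] = 1
        with pytest.warns(UserWarning, match="no windows"):
            meds = group_state_medians(part, cohort)
        assert np.isnan(meds[("A", 2)]).all()


def test_label_permutation_leaves_inertia_unchanged(planted_fc_cohort):
    cohort, _, _ = planted_fc_cohort
    pooled = np.vstack([fc.z_matrix for fc in cohort])
    est = kmeans_l1(pooled, 2, n_init=2, seed=5)
    # relabel: swap centroids and labels; inertia must be identical
    from scipy.spatial.distance import cdist

    swapped = est.cluster_centers_[::-1]
    labels = 1 - est.labels_
    D = cdist(pooled, swapped, "cityblock")
    inertia = D[np.arange(pooled.shape[0]), labels].sum()
    assert inertia == pytest.approx(est.inertia_)
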