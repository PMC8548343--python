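import numpy as np
import pytest
from scipy import stats as sps

from chronnectome import (
    cohens_d,
    group_comparison,
    hotelling_omnibus,
    hotelling_t2,
    lsd_posthoc,
    oneway_glm,
    outlier_screen,
    spearman,
    tfnbs,
)
from chronnectome.windows import pair_index


class TestOnewayGLM:
    def test_identical_constant_groups_give_zero_F(self):
        v = np.repeat(3.0, 9)
        g = np.repeat(["a", "b", "c"], 3)
        F, p, _ = oneway_glm(v, g)
        assert F == 0.0 and p == 1.0

    def test_two_group_F_equals_t_squared(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(30)
        g = np.repeat(["a", "b"], 15)
        F, _, _ = oneway_glm(v, g)
        t, _ = sps.ttest_ind(v[:15], v[15:])
        assert F == pytest.approx(t**2, abs=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(40)
        g = np.repeat(["a", "b", "c", "d"], 10)
        F, p, _ = oneway_glm(v, g)
        Fo, po = sps.f_oneway(*(v[g == lab] for lab in "abcd"))
        assert F == pytest.approx(Fo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    def test_covariate_adjustment_changes_dof(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(30)
        g = np.repeat(["a", "b", "c"], 10)
        cov = rng.standard_normal((30, 1))
        _, _, df0 = oneway_glm(v, g)
        _, _, df1 = oneway_glm(v, g, covariates=cov)
        assert df1 == df0 - 1

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_glm([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestLSD:
    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(12), rng.standard_normal(10) + 0.5
        p = lsd_posthoc(np.concatenate([a, b]),
                        ["a"] * 12 + ["b"] * 10)[("a", "b")]
        _, p_t = sps.ttest_ind(a, b)
        assert p == pytest.approx(p_t, abs=1e-10)

    def test_equal_means_give_p_one(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        for p in lsd_posthoc(v, g).values():
            assert p == pytest.approx(1.0)

    def test_three_group_hand_oracle(self):
        # groups: a=(0,2), b=(1,3), c=(4,6); means 1,2,5; MSE=2, df=3
        v = np.array([0.0, 2.0, 1.0, 3.0, 4.0, 6.0])
        g = np.array(["a", "a", "b", "b", "c", "c"])
        p = lsd_posthoc(v, g)
        se = np.sqrt(2.0 * (0.5 + 0.5))
        t_ab = (1.0 - 2.0) / se
        assert p[("a", "b")] == pytest.approx(2 * sps.t.sf(abs(t_ab), 3), abs=1e-12)
        t_ac = (1.0 - 5.0) / se
        assert p[("a", "c")] == pytest.approx(2 * sps.t.sf(abs(t_ac), 3), abs=1e-12)

    def test_no_multiplicity_adjustment(self):
        # LSD p for one pair must not depend on how many groups exist
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        p2 = lsd_posthoc(np.concatenate([a, b]), ["a"] * 8 + ["b"] * 8)
        assert len(p2) == 1  # sanity: pairwise map only


class TestCohensD:
    def test_identical_samples(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])  # zero pooled SD
        a = np.array([0.0, 1.0, 2.0])
        assert cohens_d(a, a) == 0.0

    def test_one_pooled_sd_difference(self):
        a = np.array([0.0, 1.0, 2.0])
        assert cohens_d(a + 1.0, a) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(20), rng.standard_normal(15) + 0.3
        assert cohens_d(3 * a + 2, 3 * b + 2) == pytest.approx(
            cohens_d(a, b), abs=1e-12
        )


class TestHotelling:
    def test_identical_group_means_give_zero(self):
        A = np.tile([0.3, 0.7], (6, 1)) + 0.0
        rng = np.random.default_rng(6)
        noise = rng.standard_normal((6, 2)) * 0.01
        T2, _, _ = hotelling_t2(A + noise, A + noise, drop_last=True)
        assert T2 == pytest.approx(0.0)

    def test_univariate_reduces_to_t_squared(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((12, 1))
        b = rng.standard_normal((10, 1)) + 0.4
        T2, F, p = hotelling_t2(a, b, drop_last=False)
        t, pt = sps.ttest_ind(a.ravel(), b.ravel())
        assert F == pytest.approx(t**2, abs=1e-10)
        assert p == pytest.approx(pt, abs=1e-10)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        A = rng.standard_normal((15, 3))
        B = rng.standard_normal((12, 3)) + 0.3
        T2, F, p = hotelling_t2(A, B, drop_last=False)
        res = pingouin.multivariate_ttest(A, B)
        assert T2 == pytest.approx(float(res["T2"].iloc[0]), rel=1e-9)
        assert F == pytest.approx(float(res["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(res["pval"].iloc[0]), rel=1e-9)

    def test_compositional_occupancy_auto_drops_column(self):
        rng = np.random.default_rng(9)
        A = rng.dirichlet([5, 5], size=20)
        B = rng.dirichlet([5, 5], size=18)
        T2, F, p = hotelling_t2(A, B)  # would be singular without the drop
        assert np.isfinite(F) and 0 <= p <= 1

    def test_omnibus_two_groups_consistent_with_pairwise(self):
        rng = np.random.default_rng(10)
        A = rng.standard_normal((14, 2))
        B = rng.standard_normal((13, 2)) + 0.5
        _, F_pair, p_pair = hotelling_t2(A, B, drop_last=False)
        _, F_omni, p_omni = hotelling_omnibus(
            {"a": A, "b": B}, drop_last=False
        )
        assert F_omni == pytest.approx(F_pair, rel=1e-6)
        assert p_omni == pytest.approx(p_pair, rel=1e-6)


class TestTFNBS:
    def _pairs(self, C):
        return pair_index(C)

    def test_degenerate_parameters_rank_like_abs_t(self):
        rng = np.random.default_rng(11)
        C, P = 8, 28
        A = rng.standard_normal((15, P))
        B = rng.standard_normal((15, P))
        rep = tfnbs(A, B, self._pairs(C), C, n_permutations=100, E=0.0,
                    H=0.0, seed=0)
        t = np.abs(rep.edge_t)
        dh = rep.params["dh"]
        for i in range(P):
            for j in range(P):
                if t[i] > t[j] + dh:
                    assert rep.tfnbs_score[i] >= rep.tfnbs_score[j]

    def test_fwe_p_monotone_in_score(self):
        rng = np.random.default_rng(12)
        C, P = 6, 15
        A = rng.standard_normal((12, P))
        B = rng.standard_normal((12, P)) + 0.3
        rep = tfnbs(A, B, self._pairs(C), C, n_permutations=200, seed=1)
        order = np.argsort(rep.tfnbs_score)
        assert np.all(np.diff(rep.fwe_p[order]) <= 1e-12)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(13)
        C, P = 5, 10
        A = rng.standard_normal((10, P))
        B = rng.standard_normal((10, P))
        r1 = tfnbs(A, B, self._pairs(C), C, n_permutations=150, seed=9)
        r2 = tfnbs(A, B, self._pairs(C), C, n_permutations=150, seed=9)
        assert np.array_equal(r1.fwe_p, r2.fwe_p)

    def test_planted_edge_attains_smallest_p(self):
        # single-edge mean shift of 2 pooled SD; that edge should win
        C, P = 8, 28
        wins = 0
        for rep_i in range(10):
            rng = np.random.default_rng(100 + rep_i)
            A = rng.standard_normal((20, P))
            B = rng.standard_normal((20, P))
            B[:, 5] += 2.0
            rep = tfnbs(A, B, self._pairs(C), C, n_permutations=200,
                        seed=rep_i)
            if rep.fwe_p[5] == rep.fwe_p.min():
                wins += 1
        assert wins >= 9


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0, abs=1e-12)
        rho, _ = spearman(x, -x**3)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_tied_data_matches_pearson_of_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 5.0, 7.0, 9.0])
        rho, _ = spearman(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), np.arctan(y))
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(6), np.arange(6.0))

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan, 6.0])
        rho, _ = spearman(x, y)
        assert rho == 1.0


class TestOutlierScreen:
    def test_hand_iqr_case(self):
        keep = outlier_screen(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert 4 not in keep
        assert np.array_equal(keep, [0, 1, 2, 3])

    def test_all_equal_keeps_everything(self):
        keep = outlier_screen(np.full(6, 2.0))
        assert keep.size == 6

    def test_rule_none_is_identity(self):
        keep = outlier_screen(np.array([1.0, 100.0, -50.0]), rule="none")
        assert np.array_equal(keep, [0, 1, 2])


def test_group_comparison_reports_posthocs_even_when_omnibus_ns():
    rng = np.random.default_rng(15)
    v = rng.standard_normal(30)
    g = np.repeat(["a", "b", "c"], 10)
    gc = group_comparison("metric", v, g)
    assert len(gc.pairwise) == 3
    for rec in gc.pairwise.values():
        assert 0 <= rec["lsd_p"] <= 1
        assert np.isfinite(rec["cohens_d"])
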