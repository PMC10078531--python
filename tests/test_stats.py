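"""Unit tests for the statistics engine, with independent library oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as scipy_bc

from dietscape import stats as st

# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        D = st.bray_curtis(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert D.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        D = st.bray_curtis(np.array([[1.0, 0.0], [0.0, 5.0]]))
        assert D.values[0, 1] == 1.0

    def test_hand_computed(self):
        # (1+0+1)/(3+3) = 1/3
        D = st.bray_curtis(np.array([[2.0, 1.0, 0.0], [1.0, 1.0, 1.0]]))
        assert D.values[0, 1] == pytest.approx(1 / 3)

    def test_against_scipy_oracle(self, rng):
        X = rng.random((6, 10))
        D = st.bray_curtis(X)
        for i, j in itertools.combinations(range(6), 2):
            assert D.values[i, j] == pytest.approx(scipy_bc(X[i], X[j]))

    def test_all_zero_row_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            st.bray_curtis(np.array([[1.0, 1.0], [0.0, 0.0]]))

    def test_labels_from_dataframe(self):
        df = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert st.bray_curtis(df).labels == ["a", "b"]


class TestDistanceMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            st.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            st.DistanceMatrix(["a", "b"], np.array([[1.0, 1], [1, 0]]))

    def test_condensed_length(self, rng):
        X = rng.random((5, 3))
        assert st.bray_curtis(X).condensed().shape == (10,)


# ---------------------------------------------------------------------------
# perMANOVA
# ---------------------------------------------------------------------------


def _euclidean_dm(x):
    x = np.asarray(x, float)
    D = np.abs(x[:, None] - x[None, :])
    return st.DistanceMatrix(list(range(len(x))), D)


class TestPermanova:
    def test_euclidean_limit_equals_anova_f(self, rng):
        """Univariate Euclidean pseudo-F must equal the classical ANOVA F."""
        x = rng.normal(size=18)
        g = np.repeat(["a", "b", "c"], 6)
        res = st.permanova(_euclidean_dm(x), g, n_perm=9, seed=0)
        f_classic = sps.f_oneway(x[:6], x[6:12], x[12:]).statistic
        assert res.term("factor").pseudo_f == pytest.approx(f_classic)

    def test_matches_skbio_statistic(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        X = rng.random((12, 6))
        D = st.bray_curtis(X)
        g = np.repeat(["a", "b", "c"], 4)
        mine = st.permanova(D, g, n_perm=99, seed=0).term("factor").pseudo_f
        theirs = sk_permanova(
            skbio.DistanceMatrix(D.values, [str(i) for i in D.labels]), list(g),
            permutations=0,
        )["test statistic"]
        assert mine == pytest.approx(theirs)

    def test_ss_additivity(self, rng):
        X = rng.random((15, 5))
        D = st.bray_curtis(X)
        g = np.repeat(["a", "b", "c"], 5)
        b = np.tile(["y1", "y2", "y2"], 5)
        res = st.permanova(D, g, block=b, n_perm=49, seed=0)
        ss_terms = sum(t.ss for t in res.terms)
        assert ss_terms + res.residual_ss == pytest.approx(res.total_ss, abs=1e-9)

    def test_r2_in_unit_interval(self, rng):
        X = rng.random((12, 4))
        res = st.permanova(st.bray_curtis(X), np.repeat(["a", "b"], 6), n_perm=49)
        for t in res.terms:
            assert 0 <= t.r2 <= 1

    def test_blocked_df_pattern(self, rng):
        """160 samples, year block, 15 individuals crossed with year -> df (14, 144)."""
        n_ind, per = 15, 10  # about half the samples of each individual per year
        g = np.repeat([f"id{i:02d}" for i in range(n_ind)], per)[:160]
        g = np.resize(g, 160)
        year = np.tile(["y18", "y19"], 80)
        X = rng.random((160, 8))
        res = st.permanova(st.bray_curtis(X), g, block=year, n_perm=9, seed=0)
        assert res.term("factor").df == 14
        assert res.residual_df == 144

    def test_p_never_zero_and_reproducible(self, rng):
        X = rng.random((12, 5))
        D = st.bray_curtis(X)
        g = np.repeat(["a", "b"], 6)
        r1 = st.permanova(D, g, n_perm=99, seed=5)
        r2 = st.permanova(D, g, n_perm=99, seed=5)
        assert r1.term("factor").p_perm == r2.term("factor").p_perm
        assert r1.term("factor").p_perm >= 1 / 100

    def test_single_level_raises(self, rng):
        X = rng.random((6, 3))
        with pytest.raises(ValueError, match="levels"):
            st.permanova(st.bray_curtis(X), ["a"] * 6, n_perm=9)

    def test_strata_keep_block_membership(self, rng):
        """Permutation p under strata is valid: strong block effect, null factor."""
        block = np.repeat(["b1", "b2"], 10)
        x = np.where(block == "b1", 0.0, 10.0) + rng.normal(size=20)
        g = np.tile(np.repeat(["u", "v"], 5), 2)
        res = st.permanova(_euclidean_dm(x), g, block=block, n_perm=199, seed=0)
        assert res.term("factor").p_perm > 0.05  # factor is null within blocks


class TestPairwisePermanova:
    def test_15_levels_gives_105_contrasts(self, rng):
        X = rng.random((45, 6))
        g = np.repeat([f"i{k:02d}" for k in range(15)], 3)
        out = st.pairwise_permanova(st.bray_curtis(X), g, n_perm=19, seed=0)
        assert len(out) == 105

    def test_two_levels_adjusted_equals_raw(self, rng):
        X = rng.random((10, 4))
        out = st.pairwise_permanova(
            st.bray_curtis(X), np.repeat(["a", "b"], 5), n_perm=99, seed=0
        )
        assert len(out) == 1
        assert out[0].p_adjusted == out[0].p_raw

    def test_adjusted_monotone_in_raw(self, rng):
        X = rng.random((20, 5))
        g = np.repeat(["a", "b", "c", "d"], 5)
        out = st.pairwise_permanova(st.bray_curtis(X), g, n_perm=99, seed=0)
        ordered = sorted(out, key=lambda c: c.p_raw)
        adj = [c.p_adjusted for c in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_singleton_side_skipped(self, rng):
        X = rng.random((7, 4))
        g = np.array(["a", "a", "a", "b", "b", "b", "c"])
        with pytest.warns(UserWarning, match="skipping"):
            out = st.pairwise_permanova(st.bray_curtis(X), g, n_perm=19, seed=0)
        assert len(out) == 1  # only a-vs-b survives


class TestHolm:
    def test_hand_computed_pair(self):
        np.testing.assert_allclose(st.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert st.holm_adjust([0.3])[0] == 0.3

    def test_all_ones(self):
        np.testing.assert_allclose(st.holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            st.holm_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=12))
    def test_dominates_bonferroni(self, ps):
        holm = st.holm_adjust(ps)
        bonf = np.minimum(1.0, np.asarray(ps) * len(ps))
        assert (holm <= bonf + 1e-12).all()

    @settings(max_examples=50, deadline=None)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=12))
    def test_in_unit_interval(self, ps):
        holm = st.holm_adjust(ps)
        assert ((holm >= 0) & (holm <= 1)).all()


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        D = st.bray_curtis(rng.random((8, 5)))
        res = st.mantel(D, D, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_transform_r_one(self, rng):
        D1 = st.bray_curtis(rng.random((8, 5)))
        D2 = st.DistanceMatrix(D1.labels, 0.3 * D1.values)
        assert st.mantel(D1, D2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_r_equals_pearson_on_triangles(self, rng):
        D1 = st.bray_curtis(rng.random((9, 6)))
        D2 = st.bray_curtis(rng.random((9, 6)))
        D2 = st.DistanceMatrix(D1.labels, D2.values)
        res = st.mantel(D1, D2, n_perm=9, seed=0)
        r_oracle = sps.pearsonr(D1.condensed(), D2.condensed()).statistic
        assert res.r == pytest.approx(r_oracle)

    def test_zero_variance_raises(self):
        flat = st.DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        D = st.bray_curtis(np.random.default_rng(1).random((3, 4)))
        flat2 = st.DistanceMatrix(D.labels, flat.values)
        with pytest.raises(ValueError, match="variance"):
            st.mantel(flat2, D, n_perm=9)

    def test_label_mismatch_raises(self, rng):
        D1 = st.bray_curtis(pd.DataFrame(rng.random((4, 3)), index=list("abcd")))
        D2 = st.bray_curtis(pd.DataFrame(rng.random((4, 3)), index=list("abce")))
        with pytest.raises(ValueError, match="labels"):
            st.mantel(D1, D2, n_perm=9)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


class TestNmds:
    def test_euclidean_embedding_near_zero_stress(self, rng):
        pts = rng.random((10, 2))
        diff = pts[:, None] - pts[None, :]
        D = st.DistanceMatrix(list(range(10)), np.hypot(diff[..., 0], diff[..., 1]))
        res = st.nmds(D, k=2, seed=0)
        assert res.stress < 0.01

    def test_stress_history_nonincreasing(self, rng):
        D = st.bray_curtis(rng.random((12, 8)))
        res = st.nmds(D, k=2, seed=0)
        h = res.stress_history
        assert all(a >= b - 1e-12 for a, b in zip(h, h[1:]))

    def test_rotation_invariance_of_stress(self, rng):
        D = st.bray_curtis(rng.random((10, 6)))
        res = st.nmds(D, k=2, seed=0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = res.configuration @ R.T

        ii, jj = np.tril_indices(10, -1)
        def stress_of(X):
            d = np.hypot(*(X[:, None] - X[None]).transpose(2, 0, 1))[ii, jj]
            from scipy.optimize import isotonic_regression
            order = np.argsort(D.values[ii, jj], kind="stable")
            dhat = np.empty_like(d)
            dhat[order] = isotonic_regression(d[order]).x
            return np.sqrt(((d - dhat) ** 2).sum() / (d**2).sum())

        assert stress_of(rotated) == pytest.approx(stress_of(res.configuration))

    def test_k_too_large_raises(self, rng):
        D = st.bray_curtis(rng.random((4, 3)))
        with pytest.raises(ValueError):
            st.nmds(D, k=4)


# ---------------------------------------------------------------------------
# OLS + AICc
# ---------------------------------------------------------------------------


class TestOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = st.ols_fit(2 * x, x)
        assert fit.params[1] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_orthogonal_slope_zero(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert st.ols_fit(y, x).params[1] == pytest.approx(0.0, abs=1e-12)

    def test_slope_recovery(self, rng):
        x = rng.normal(size=1000)
        y = 3 * x + rng.normal(size=1000)
        fit = st.ols_fit(y, x)
        assert abs(fit.params[1] - 3) < 3 * fit.se[1]

    def test_against_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(30, 2))
        y = 1 + X @ [0.5, -2.0] + rng.normal(size=30)
        fit = st.ols_fit(y, X)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.params, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.pvalues, ref.pvalues, rtol=1e-8)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj)

    def test_rank_deficient_raises(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            st.ols_fit(np.arange(6.0), X)


class TestAicc:
    def _fit(self, rng, p):
        X = rng.normal(size=(20, p))
        y = rng.normal(size=20)
        return st.ols_fit(y, X)

    def test_single_model_weight_one(self, rng):
        rank = st.aicc_rank([("m", self._fit(rng, 1))], 20)
        assert rank.models[0].weight == pytest.approx(1.0)
        assert rank.models[0].delta_aicc == 0.0

    def test_identical_models_split_weight(self, rng):
        f = self._fit(rng, 1)
        rank = st.aicc_rank([("a", f), ("b", f)], 20)
        assert [m.weight for m in rank.models] == pytest.approx([0.5, 0.5])

    def test_delta_two_weights(self):
        # delta=(0,2) -> weights 1/(1+e^-1), e^-1/(1+e^-1) = (0.731, 0.269)
        w = np.exp([0, -1.0])
        w = w / w.sum()
        assert w[0] == pytest.approx(0.731, abs=1e-3)
        # engineer two models with AICc exactly 2 apart via RSS manipulation
        n, k = 20, 3  # one predictor: coefs 2 + variance
        rss1 = 1.0
        rss2 = rss1 * np.exp(2 / n)  # AIC difference of exactly 2, same k
        f1 = st.OlsResult(np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2),
                          0, 0, rss1, n, 2, ["intercept", "x"])
        f2 = st.OlsResult(np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2),
                          0, 0, rss2, n, 2, ["intercept", "x"])
        rank = st.aicc_rank([("m1", f1), ("m2", f2)], n)
        assert rank.models[0].weight == pytest.approx(0.731, abs=1e-3)
        assert rank.models[1].weight == pytest.approx(0.269, abs=1e-3)

    def test_weights_sum_to_one(self, rng):
        rank = st.aicc_rank(
            [("a", self._fit(rng, 1)), ("b", self._fit(rng, 2)), ("c", self._fit(rng, 3))],
            20,
        )
        assert sum(m.weight for m in rank.models) == pytest.approx(1.0)

    def test_small_n_raises(self, rng):
        f = self._fit(rng, 1)
        with pytest.raises(ValueError):
            st.aicc_rank([("m", f)], 4)


# ---------------------------------------------------------------------------
# Welch
# ---------------------------------------------------------------------------


class TestWelch:
    def test_identical_groups_t_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert st.welch_t(x, x).t == 0.0

    def test_equal_n_equal_var_matches_pooled(self, rng):
        x1 = rng.normal(size=12)
        x2 = rng.normal(size=12)
        mine = st.welch_t(x1, x2)
        pooled = sps.ttest_ind(x1, x2, equal_var=True)
        assert mine.t == pytest.approx(pooled.statistic)

    def test_against_scipy_oracle(self, rng):
        x1 = rng.normal(size=8)
        x2 = rng.normal(loc=1, scale=2, size=15)
        mine = st.welch_t(x1, x2)
        ref = sps.ttest_ind(x1, x2, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)
        assert mine.df == pytest.approx(ref.df)

    def test_zero_variance_both_raises(self):
        with pytest.raises(ValueError):
            st.welch_t([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# Condition index
# ---------------------------------------------------------------------------


class TestConditionIndex:
    def test_correlated_variables_proportional_scores(self, rng):
        v = rng.normal(size=30)
        df = pd.DataFrame({"fat": v, "muscle": 2 * v + 5})
        res = st.condition_index(df)
        z = (v - v.mean()) / v.std(ddof=1)
        corr = np.corrcoef(res.scores, z)[0, 1]
        assert abs(corr) == pytest.approx(1.0)

    def test_sign_anchored_to_first_column(self, rng):
        v = rng.normal(size=50)
        df = pd.DataFrame({"fat": v, "other": v + 0.1 * rng.normal(size=50)})
        res = st.condition_index(df)
        assert res.loadings["fat"] > 0
        flipped = st.condition_index(-df)
        # orientation contract: anchor loading positive either way
        assert flipped.loadings["fat"] > 0

    def test_isotropic_explained_variance(self, rng):
        p = 4
        df = pd.DataFrame(rng.normal(size=(3000, p)))
        res = st.condition_index(df, anchor=0)
        assert res.explained_variance_ratio == pytest.approx(1 / p, abs=0.05)

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame(
            {"fat": rng.normal(size=10), "c": 1.0, "m": rng.normal(size=10)}
        )
        with pytest.warns(UserWarning, match="constant"):
            res = st.condition_index(df)
        assert "c" not in res.loadings.index

    def test_missing_values_raise(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            st.condition_index(df)
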