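"""Statistical preprocessing: transforms, tests, FDR, bootstrap selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disconseq import (
    bh_adjust,
    bootstrap_rank_selection,
    group_ttest,
    log_transform,
    normality_check,
    regress_out_covariates,
)


def bh_bruteforce(p):
    """Step-up BH by direct enumeration: p_adj(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        adj[order[i]] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    return adj


class TestLogTransform:
    def test_zero_maps_to_log_epsilon(self):
        out = log_transform(np.zeros((2, 2)), epsilon=1e-6)
        np.testing.assert_allclose(out, np.log(1e-6))

    def test_monotone_and_invertible(self):
        rng = np.random.default_rng(0)
        x = rng.random((50, 3))
        y = log_transform(x, 1e-6)
        col = x[:, 0]
        assert (np.argsort(col) == np.argsort(y[:, 0])).all()
        np.testing.assert_allclose(np.exp(y) - 1e-6, x, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([[-0.1]]))


class TestNormalityCheck:
    def test_normal_column_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        reject = 0
        for _ in range(200):
            df = normality_check(rng.standard_normal((500, 1)))
            reject += df["p"].iloc[0] < 0.05
        assert 2 <= reject <= 25  # ~5% of 200, generous binomial band

    def test_lognormal_column_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            df = normality_check(np.exp(rng.standard_normal((200, 1))))
            hits += df["p"].iloc[0] < 0.05
        assert hits >= 19

    def test_constant_column_skipped(self):
        df = normality_check(np.column_stack([np.ones(10), np.arange(10.0)]))
        assert bool(df["skipped"].iloc[0]) and not bool(df["skipped"].iloc[1])
        assert np.isnan(df["W"].iloc[0])


class TestRegressOutCovariates:
    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(3)
        n = 80
        age = rng.uniform(25, 60, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.01 * age[:, None] + 0.2 * sex[:, None] + rng.standard_normal((n, 4))
        res = regress_out_covariates(y, age, sex)
        assert abs(res.mean(axis=0)).max() < 1e-10
        for j in range(4):
            assert abs(np.corrcoef(res[:, j], age)[0, 1]) < 1e-10
            assert abs(np.corrcoef(res[:, j], sex)[0, 1]) < 1e-10

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(4)
        n = 50
        age = rng.uniform(25, 60, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = rng.standard_normal((n, 2))
        X = np.column_stack([np.ones(n), age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # normal equations oracle
        np.testing.assert_allclose(regress_out_covariates(y, age, sex), y - X @ beta, atol=1e-10)

    def test_collinear_covariates_rejected(self):
        with pytest.raises(ValueError, match="collinear|constant"):
            regress_out_covariates(np.random.default_rng(0).random((10, 2)), np.ones(10), np.ones(10))


class TestGroupTTest:
    def test_identical_groups_t_zero_p_one(self):
        x = np.tile([[1.0], [1.0], [2.0], [2.0]], (1, 1))
        t, p, undef = group_ttest(np.vstack([x, x]), [0, 0, 0, 0, 1, 1, 1, 1])
        assert t[0] == 0.0 and p[0] == 1.0 and not undef[0]

    def test_sign_convention_group1_larger_positive(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([np.zeros(4), np.ones(4)]) + 1e-3 * rng.standard_normal(8)
        t, _, _ = group_ttest(x[:, None], [0] * 4 + [1] * 4)
        assert t[0] > 50

    def test_matches_pooled_variance_formula(self):
        a = np.array([3.1, 2.8, 3.5, 3.0, 2.9])  # group 0
        b = np.array([3.9, 4.1, 3.7, 4.4, 3.6])  # group 1
        t, p, _ = group_ttest(np.concatenate([a, b])[:, None], [0] * 5 + [1] * 5)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t_hand = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        np.testing.assert_allclose(t[0], t_hand, rtol=1e-12)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(6)
        x = rng.random((30, 5))
        g = rng.integers(0, 2, 30)
        g[:2], g[-2:] = 0, 1  # ensure both groups
        t1, _, _ = group_ttest(x, g)
        t2, _, _ = group_ttest(x, 1 - g)
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_zero_variance_unequal_means_flagged(self):
        x = np.array([1.0, 1.0, 2.0, 2.0])[:, None]
        t, p, undef = group_ttest(x, [0, 0, 1, 1])
        assert undef[0] and np.isnan(t[0])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adj, sig = bh_adjust([0.03])
        assert adj[0] == 0.03 and sig[0]

    def test_ties_all_equal(self):
        adj, _ = bh_adjust([0.04] * 6)
        np.testing.assert_allclose(adj, 0.04)

    def test_matches_bruteforce_step_up(self):
        p = [0.01, 0.02, 0.03, 0.20]
        adj, _ = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_bruteforce(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_bruteforce_agreement_and_permutation_invariance(self, p):
        adj, _ = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_bruteforce(p), atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm, _ = bh_adjust(np.asarray(p)[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestBootstrapRankSelection:
    @staticmethod
    def _shift_cohort(rng, n=120, p=12, shifted=4, delta=2.0):
        g = np.array([0] * (n // 2) + [1] * (n // 2))
        x = rng.standard_normal((n, p))
        x[g == 1, :shifted] += delta
        return x, g

    def test_top_k_equals_p_selects_all(self):
        rng = np.random.default_rng(0)
        x, g = self._shift_cohort(rng)
        res = bootstrap_rank_selection(x, g, n_boot=10, top_k=12, seed=1)
        assert sorted(res.selected_regions) == sorted(res.region_ids)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(1)
        x, g = self._shift_cohort(rng)
        r1 = bootstrap_rank_selection(x, g, n_boot=20, top_k=4, seed=7)
        r2 = bootstrap_rank_selection(x, g, n_boot=20, top_k=4, seed=7)
        assert r1.selected_regions == r2.selected_regions
        np.testing.assert_array_equal(r1.mean_ranks, r2.mean_ranks)

    def test_identity_bootstrap_reduces_to_full_sample_t_ranking(self):
        rng = np.random.default_rng(2)
        x, g = self._shift_cohort(rng)
        res = bootstrap_rank_selection(x, g, n_boot=1, top_k=5, seed=0, resample=False)
        t, _, _ = group_ttest(x, g)
        expect = [res.region_ids[j] for j in np.argsort(-t)[:5]]
        assert res.selected_regions == expect

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(3)
        x, g = self._shift_cohort(rng, n=200, p=20, shifted=6, delta=2.0)
        res = bootstrap_rank_selection(x, g, n_boot=50, top_k=6, seed=4)
        assert sorted(res.selected_regions) == [str(j) for j in range(6)]

    def test_result_table_is_tidy(self):
        rng = np.random.default_rng(4)
        x, g = self._shift_cohort(rng)
        df = bootstrap_rank_selection(x, g, n_boot=10, top_k=3, seed=0).to_frame()
        assert list(df.columns) == ["region_id", "t", "p", "p_adj", "mean_rank", "selected"]
        assert df["selected"].sum() == 3
        assert len(df) == 12
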