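import numpy as np
import pytest
from scipy import stats as sps

from edgedyn.stats import (
    chi_square_test,
    cohens_d_ci,
    combat_fit_apply,
    fdr_bh,
    spearman,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_samples(self, rng):
        x = rng.normal(size=10)
        cmp = two_sample_t(x, x)
        assert cmp.t_statistic == 0.0 and cmp.p_value == pytest.approx(1.0)

    def test_df_is_pooled(self, rng):
        cmp = two_sample_t(rng.normal(size=211), rng.normal(size=210))
        assert cmp.df == 419

    def test_matches_scipy(self, rng):
        a, b = rng.normal(size=14), rng.normal(1.0, 2.0, size=9)
        cmp = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert cmp.t_statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert cmp.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_null_p_uniform(self, rng):
        ps = [
            two_sample_t(rng.normal(size=15), rng.normal(size=15)).p_value
            for _ in range(500)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.001

    def test_too_small(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestCohensD:
    def test_equal_means_symmetric_ci(self):
        d, (lo, hi) = cohens_d_ci(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert d == 0.0 and lo == pytest.approx(-hi)

    def test_sign_convention(self):
        d, _ = cohens_d_ci(1.0, 1.0, 10, 0.0, 1.0, 10)
        assert d > 0

    def test_pooled_sd_formula(self):
        d, _ = cohens_d_ci(2.0, 3.0, 5, 1.0, 4.0, 7)
        sp = np.sqrt((4 * 9 + 6 * 16) / 10)
        assert d == pytest.approx(1.0 / sp)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            cohens_d_ci(1.0, 0.0, 5, 2.0, 0.0, 5)
        with pytest.raises(ValueError):
            cohens_d_ci(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestChiSquare:
    def test_uniform_table(self):
        stat, df, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_df_2x3(self):
        _, df, _ = chi_square_test([[5, 6, 7], [8, 9, 10]])
        assert df == 2

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            obs = rng.integers(1, 30, size=(3, 4)).astype(float)
            stat, df, _ = chi_square_test(obs)
            total = obs.sum()
            expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
            manual = ((obs - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(manual, abs=1e-10)
            assert df == 6

    def test_zero_marginal(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [3, 4]])


class TestFdrBh:
    def test_hand_step_up(self):
        adj, rej = fdr_bh([0.005, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.015, 0.04, 0.04])
        assert rej.all()

    def test_all_ones(self):
        adj, rej = fdr_bh([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_single(self):
        adj, _ = fdr_bh([0.03])
        assert adj[0] == 0.03

    def test_matches_brute_force_rejection_set(self, rng):
        for _ in range(50):
            p = rng.random(12)
            alpha = 0.1
            _, rej = fdr_bh(p, alpha=alpha)
            # brute-force definition: max k with p_(k) <= k * alpha / m
            srt = np.sort(p)
            m = len(p)
            ks = [k for k in range(1, m + 1) if srt[k - 1] <= k * alpha / m]
            if ks:
                cut = srt[max(ks) - 1]
                expected = p <= cut
            else:
                expected = np.zeros(m, dtype=bool)
            np.testing.assert_array_equal(rej, expected)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.random(30)
        adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSpearman:
    def test_monotone(self):
        r = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0)

    def test_antimonotone(self):
        x = np.arange(10.0)
        r = spearman(x, -x)
        assert r.rho == pytest.approx(-1.0)

    def test_ties_match_pearson_on_average_ranks(self, rng):
        x = rng.integers(0, 4, size=40).astype(float)
        y = rng.integers(0, 4, size=40).astype(float)
        r = spearman(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert r.rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestCombat:
    def make_data(self, rng, n_per_site=20, n_feat=5, shift=5.0, group_effect=1.0):
        n = 2 * n_per_site
        sites = np.array([0] * n_per_site + [1] * n_per_site)
        group = np.tile([0.0, 1.0], n // 2)  # balanced within each site
        y = rng.normal(size=(n, n_feat))
        y[sites == 1] += shift
        y += group[:, None] * group_effect
        return y, sites, group

    def test_single_site_identity(self, rng):
        y = rng.normal(size=(10, 4))
        out, model = combat_fit_apply(y, np.zeros(10))
        np.testing.assert_array_equal(out, y)

    def test_site_shift_removed(self, rng):
        y, sites, group = self.make_data(rng, shift=5.0, group_effect=0.0)
        out, _ = combat_fit_apply(y, sites)
        before = np.abs(y[sites == 0].mean(0) - y[sites == 1].mean(0))
        after = np.abs(out[sites == 0].mean(0) - out[sites == 1].mean(0))
        assert np.all(after < 0.1 * before)

    def test_group_effect_preserved(self, rng):
        y, sites, group = self.make_data(rng, shift=5.0, group_effect=1.0)
        out, _ = combat_fit_apply(y, sites, covariates=group[:, None])
        before = y[group == 1].mean(0) - y[group == 0].mean(0)
        after = out[group == 1].mean(0) - out[group == 0].mean(0)
        # harmonization must not erode the retained covariate effect
        np.testing.assert_allclose(after, before, atol=0.15)
        assert abs(after.mean() - 1.0) < 0.15

    def test_null_site_effect_near_identity(self, rng):
        y, sites, _ = self.make_data(rng, shift=0.0, group_effect=0.0)
        out, _ = combat_fit_apply(y, sites)
        mean_abs_change = np.abs(out - y).mean()
        assert mean_abs_change < 0.25 * y.std()

    def test_scale_effect_shrunk(self, rng):
        y, sites, _ = self.make_data(rng, shift=0.0, group_effect=0.0)
        y[sites == 1] *= 3.0
        out, _ = combat_fit_apply(y, sites)
        sd0 = out[sites == 0].std(0, ddof=1)
        sd1 = out[sites == 1].std(0, ddof=1)
        assert np.all(np.abs(sd1 / sd0 - 1) < 0.35)

    def test_singleton_site_errors(self, rng):
        y = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="site"):
            combat_fit_apply(y, np.array([0, 0, 0, 0, 1]))

    def test_model_delta_positive(self, rng):
        y, sites, _ = self.make_data(rng)
        _, model = combat_fit_apply(y, sites)
        assert np.all(model.delta_star > 0)
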