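"""The five dispersion tests against hand calculations and independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from vqtlkit.preprocess import group_median_deviations
from vqtlkit.vartests import (
    bf_test,
    dglm_test,
    drm_test,
    kw_test,
    quail_test,
    quail_beta_qi,
)

from conftest import make_deviations, make_residuals, random_dispersion_data


def random_deviation_instance(rng, with_ties=False):
    n = int(rng.integers(20, 80))
    groups = rng.integers(0, 3, n)
    while np.unique(groups).size < 2:
        groups = rng.integers(0, 3, n)
    values = rng.exponential(1.0, n)
    if with_ties:
        values = np.round(values, 1)
    return make_deviations(values, groups)


class TestKW:
    def test_hand_computed_two_groups(self):
        result = kw_test(make_deviations([1, 2, 3, 4], [0, 0, 1, 1]))
        assert result.statistic == pytest.approx(12 / 5)
        assert result.df == (1,)
        assert result.p_value == pytest.approx(stats.chi2.sf(2.4, 1))

    def test_identical_group_multisets_give_zero(self):
        result = kw_test(make_deviations([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1]))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_all_tied_is_degenerate(self):
        result = kw_test(make_deviations(np.ones(9), [0, 0, 0, 1, 1, 1, 2, 2, 2]))
        assert result.degenerate and result.p_value == 1.0

    @pytest.mark.parametrize("seed,ties", [(s, t) for s in range(6)
                                           for t in (False, True)])
    def test_matches_scipy_kruskal(self, seed, ties):
        dev = random_deviation_instance(np.random.default_rng(seed), ties)
        samples = [dev.values[dev.groups == g] for g in np.unique(dev.groups)]
        oracle = stats.kruskal(*samples)
        result = kw_test(dev)
        assert result.statistic == pytest.approx(oracle.statistic, abs=1e-10)
        assert result.p_value == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_rank_invariance_under_monotone_transform(self, rng):
        dev = random_deviation_instance(rng)
        cubed = make_deviations(dev.values ** 3, dev.groups)
        assert kw_test(dev).statistic == pytest.approx(kw_test(cubed).statistic)


class TestBF:
    def test_hand_computed_two_groups(self):
        result = bf_test(make_deviations([1, 2, 3, 4], [0, 0, 1, 1]))
        assert result.statistic == pytest.approx(8.0)
        assert result.df == (1, 2)
        assert result.p_value == pytest.approx(stats.f.sf(8.0, 1, 2))
        # equals the squared-t2 tail: F(1, k) = t(k)^2
        assert result.p_value == pytest.approx(2 * stats.t.sf(np.sqrt(8), 2))

    def test_equal_group_means_give_zero(self):
        result = bf_test(make_deviations([1, 3, 1, 3], [0, 0, 1, 1]))
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_anova_f_on_indicators(self, seed):
        dev = random_deviation_instance(np.random.default_rng(seed))
        # brute-force OLS of D on two genotype indicators; ANOVA F via RSS
        d, g = dev.values, dev.groups
        X = np.column_stack([np.ones_like(d), (g == 1).astype(float),
                             (g == 2).astype(float)])
        X = X[:, [True, (g == 1).any(), (g == 2).any()]]
        beta, *_ = np.linalg.lstsq(X, d, rcond=None)
        rss_full = ((d - X @ beta) ** 2).sum()
        rss_null = ((d - d.mean()) ** 2).sum()
        m = np.unique(g).size
        f_oracle = ((rss_null - rss_full) / (m - 1)) / (rss_full / (d.size - m))
        result = bf_test(dev)
        assert result.statistic == pytest.approx(f_oracle, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_brown_forsythe(self, seed):
        """Full pipeline equals scipy's median-centred Levene on residual groups."""
        rng = np.random.default_rng(seed)
        e, g = random_dispersion_data(rng, n=200, sigma_slope=0.4)
        dev = group_median_deviations(make_residuals(e, g))
        oracle = stats.levene(*[e[g == lv] for lv in np.unique(g)],
                              center="median")
        result = bf_test(dev)
        assert result.statistic == pytest.approx(oracle.statistic, abs=1e-10)
        assert result.p_value == pytest.approx(oracle.pvalue, abs=1e-10)


class TestDRM:
    def test_hand_computed_slope_and_t(self):
        result = drm_test(make_deviations([1, 2, 3, 4], [0, 0, 1, 1]))
        assert result.effect == pytest.approx(2.0)
        assert result.statistic == pytest.approx(2 * np.sqrt(2), abs=1e-12)
        assert result.df == (2,)
        assert result.p_value == pytest.approx(2 * stats.t.sf(2 * np.sqrt(2), 2))

    def test_constant_deviations_are_null(self):
        result = drm_test(make_deviations(np.full(6, 2.0), [0, 0, 1, 1, 2, 2]))
        assert result.effect == 0.0 and result.p_value == 1.0

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant"):
            drm_test(make_deviations([1.0, 2, 3], [1, 1, 1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_ols(self, seed):
        import statsmodels.api as sm
        dev = random_deviation_instance(np.random.default_rng(seed))
        fit = sm.OLS(dev.values,
                     sm.add_constant(dev.groups.astype(float))).fit()
        result = drm_test(dev)
        assert result.effect == pytest.approx(fit.params[1], abs=1e-10)
        assert result.p_value == pytest.approx(fit.pvalues[1], abs=1e-10)


class TestDGLM:
    def test_recovers_planted_dispersion_slope(self):
        rng = np.random.default_rng(5)
        e, g = random_dispersion_data(rng, n=20_000, sigma_slope=0.5)
        result = dglm_test(make_residuals(e, g))
        assert result.converged
        assert abs(result.effect - 0.5) < 3 * result.se_effect

    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(6)
        e, g = random_dispersion_data(rng, n=20_000, sigma_slope=0.0)
        result = dglm_test(make_residuals(e, g))
        assert abs(result.effect) < 3 * result.se_effect

    @pytest.mark.parametrize("seed", range(3))
    def test_dispersion_score_equations_stationary(self, seed):
        """At convergence the gamma-GLM score sum Z'W(d/mu - 1) vanishes."""
        rng = np.random.default_rng(seed)
        e, g = random_dispersion_data(rng, n=2_000, sigma_slope=0.3)
        res = make_residuals(e, g)
        result = dglm_test(res)
        x = res.groups.astype(float)
        Z = np.column_stack([np.ones_like(x), x])
        sigma2 = np.exp(Z @ result.info["gamma"])
        r2 = np.maximum((e - Z @ result.info["beta"]) ** 2, 1e-10 * e.var())
        score = Z.T @ (0.5 * (r2 / sigma2 - 1.0))
        assert np.linalg.norm(score) < 1e-6 * e.size

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels_alternation(self, seed):
        """Independent route: alternate statsmodels WLS + Gamma GLM to a fixpoint."""
        import statsmodels.api as sm
        rng = np.random.default_rng(100 + seed)
        e, g = random_dispersion_data(rng, n=3_000, sigma_slope=0.4)
        x = g.astype(float)
        X = sm.add_constant(x)
        sigma2 = np.full(e.size, e.var())
        gamma = None
        for _ in range(200):
            mean_fit = sm.WLS(e, X, weights=1.0 / sigma2).fit()
            d = np.maximum(mean_fit.resid ** 2, 1e-10 * e.var())
            disp_fit = sm.GLM(d, X, family=sm.families.Gamma(sm.families.links.Log()),
                              var_weights=np.full(e.size, 0.5)).fit(scale=1.0)
            new_sigma2 = disp_fit.mu
            if np.max(np.abs(np.log(new_sigma2) - np.log(sigma2))) < 1e-10:
                sigma2 = new_sigma2
                gamma = disp_fit
                break
            sigma2 = new_sigma2
            gamma = disp_fit
        result = dglm_test(make_residuals(e, g))
        assert result.effect == pytest.approx(gamma.params[1], abs=1e-6)
        assert result.se_effect == pytest.approx(gamma.bse[1], rel=1e-4)

    def test_int_variant_is_rank_based(self, rng):
        e, g = random_dispersion_data(rng, n=500, sigma_slope=0.3)
        res = make_residuals(e, g)
        res_cubed = make_residuals(np.sign(e) * np.abs(e) ** 3, g)
        a = dglm_test(res, apply_int=True)
        b = dglm_test(res_cubed, apply_int=True)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-8)


class TestQUAIL:
    def test_toy_effect_matches_bruteforce_quantile_regressions(self):
        """K=2 rectangle sum equals exhaustive check-loss minimisation.

        The toy data are in general position (each of the four quantile
        regressions has a unique vertex solution), so the enumeration over
        sample pairs is an exact oracle.
        """
        rng = np.random.default_rng(5)
        e = rng.normal(size=12)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2], dtype=float)
        e = e * (1 + 0.5 * x)

        def check_loss(a, b, tau):
            r = e - a - b * x
            return np.sum(r * (tau - (r < 0)))

        def brute_slope(tau):
            # an optimal quantile-regression line passes through two samples
            best, best_loss = 0.0, np.inf
            for i, j in itertools.combinations(range(12), 2):
                if x[i] == x[j]:
                    continue
                b = (e[i] - e[j]) / (x[i] - x[j])
                a = e[i] - b * x[i]
                loss = check_loss(a, b, tau)
                if loss < best_loss - 1e-12:
                    best, best_loss = b, loss
            return best

        k = 2
        taus = (2 * np.arange(1, k + 1) - 1) / (4.0 * k)
        expected = sum(brute_slope(1 - t) - brute_slope(t) for t in taus) / (2 * k)
        assert quail_beta_qi(e, x, k) == pytest.approx(expected, abs=1e-8)

    def test_direction_and_significance_under_spread_increase(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, 20_000)
        e = rng.normal(0, 1 + 0.5 * g)
        result = quail_test(make_residuals(e, g), k=100)
        assert result.statistic > 0
        assert result.p_value < 1e-6

    def test_effect_estimate_positive_under_spread_increase(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.4, 4_000)
        e = rng.normal(0, 1 + 0.5 * g)
        result = quail_test(make_residuals(e, g), k=8, compute_effect=True)
        assert result.effect > 0

    def test_null_statistic_is_modest(self, rng):
        e, g = random_dispersion_data(rng, n=5_000, sigma_slope=0.0)
        result = quail_test(make_residuals(e, g), k=100)
        assert result.p_value > 1e-3

    def test_k_exceeding_n_raises(self, rng):
        e, g = random_dispersion_data(rng, n=50)
        with pytest.raises(ValueError, match="K exceeds"):
            quail_test(make_residuals(e, g), k=100)


class TestPipelineInvariances:
    @pytest.mark.parametrize("method", ["KW", "BF", "DRM", "DGLM", "QUAIL"])
    def test_invariant_to_trait_shift_and_covariate_scale(self, method, rng):
        from vqtlkit.scan import analyze_variant
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.5 * g + cov @ [1.0, -0.5] + rng.normal(0, 1 + 0.2 * g)
        a = analyze_variant(y, g, cov, method, quail_k=20)
        b = analyze_variant(y + 100.0, g, cov * 7.5, method, quail_k=20)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
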