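"""Model-fitting tests: the IRLS NB GLM, the Laplace NB GLMM, and the
agreement between the two independent routes."""

import numpy as np
import pytest

from mixedde import NBGLM, NBGLMM, fit_nb_glmm, wald_test
from mixedde.glmm import NBGLMMResults, fit_matrix


def _nb(rng, mean, theta):
    return rng.poisson(rng.gamma(theta, np.asarray(mean) / theta))


class TestNBGLM:
    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        cond = np.r_[np.zeros(30), np.ones(30)]
        y = _nb(rng, np.exp(3.0 + 0.8 * cond), 5.0)
        fit = NBGLM(y, cond).fit()
        X = np.column_stack([np.ones(60), cond])
        ref = sm.NegativeBinomial(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params[:2], rtol=2e-3)
        assert fit.theta == pytest.approx(1.0 / ref.params[-1], rel=0.02)

    def test_offset_shifts_intercept_only(self):
        rng = np.random.default_rng(1)
        cond = np.r_[np.zeros(20), np.ones(20)]
        y = _nb(rng, np.exp(4.0 + 0.5 * cond), 8.0)
        f0 = NBGLM(y, cond).fit()
        f1 = NBGLM(y, cond, offset=np.full(40, 0.7)).fit()
        assert f1.params[0] == pytest.approx(f0.params[0] - 0.7, abs=1e-5)
        assert f1.params[1] == pytest.approx(f0.params[1], abs=1e-5)


class TestGLMMReduction:
    def test_no_random_term_matches_irls_glm(self):
        """Two independent routes to the same NB GLM optimum.

        The Laplace kernel with no random term and the independent IRLS
        route maximize the same likelihood in beta at a common size
        parameter; coefficients agree to 1e-3 relative. (The size
        parameter itself differs by design between the two routes —
        adjusted vs plain profile — and with unequal offsets beta
        depends weakly on it, so the IRLS oracle is evaluated at the
        kernel's theta.)
        """
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(4, 10)) * 2
            cond = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            off = rng.uniform(-0.2, 0.2, n)
            mu = np.exp(rng.uniform(2, 6) + rng.uniform(-1, 1) * cond + off)
            y = _nb(rng, mu, rng.uniform(2, 20))
            if y.sum() == 0 or (y[cond == 0].sum() == 0) or (y[cond == 1].sum() == 0):
                continue
            a = fit_nb_glmm(y, cond, offset=off)
            b = NBGLM(y, cond, offset=off).fit(theta_fixed=a.theta)
            np.testing.assert_allclose(a.params, b.params, rtol=1e-3, atol=1e-4)

    def test_no_offset_full_routes_agree(self):
        # with a constant offset the coefficient optimum is free of the
        # size parameter, so the two complete routes agree end to end
        rng = np.random.default_rng(7)
        cond = np.r_[np.zeros(8), np.ones(8)]
        y = _nb(rng, np.exp(4.0 + 0.6 * cond), 6.0)
        a = fit_nb_glmm(y, cond)
        b = NBGLM(y, cond).fit()
        np.testing.assert_allclose(a.params, b.params, rtol=1e-4)

    def test_boundary_refit_equals_no_group_fit(self):
        # Poisson-like data: the random-intercept variance collapses and
        # the refit equals the fixed-effects-only fit
        rng = np.random.default_rng(3)
        n = 12
        cond = np.r_[np.zeros(6), np.ones(6)]
        y = rng.poisson(np.exp(4.0 + 0.3 * cond))
        with_groups = fit_nb_glmm(y, cond, groups=[f"s{j}" for j in range(n)])
        without = fit_nb_glmm(y, cond)
        assert with_groups.boundary
        assert with_groups.sigma2 == 0.0
        np.testing.assert_allclose(
            with_groups.params, without.params, rtol=1e-3
        )


class TestGLMMFit:
    def test_deterministic(self):
        rng = np.random.default_rng(4)
        cond = np.r_[np.zeros(6), np.ones(6)]
        y = _nb(rng, np.exp(5 + 0.5 * cond), 4.0)
        g = [f"s{j}" for j in range(12)]
        f1 = fit_nb_glmm(y, cond, groups=g)
        f2 = fit_nb_glmm(y, cond, groups=g)
        assert f1.params.tolist() == f2.params.tolist()
        assert f1.theta == f2.theta and f1.sigma2 == f2.sigma2

    def test_variance_components_recovered_with_replicated_groups(self):
        """beta/theta/sigma recovery when groups hold several samples.

        10 groups of 10 samples, half the groups per condition; true
        beta=ln 2, theta=10, sigma=0.4.
        """
        rng = np.random.default_rng(5)
        q, per = 10, 10
        n = q * per
        gidx = np.repeat(np.arange(q), per)
        cond = (gidx >= q // 2).astype(float)
        groups = [f"i{g}" for g in gidx]
        betas, thetas, sigmas = [], [], []
        for _ in range(60):
            b = rng.normal(0, 0.4, q)
            mu = np.exp(np.log(100) + np.log(2) * cond + b[gidx])
            y = _nb(rng, mu, 10.0)
            f = fit_nb_glmm(y, cond, groups=groups)
            betas.append(f.params[1])
            thetas.append(f.theta)
            sigmas.append(np.sqrt(f.sigma2))
        assert abs(np.mean(betas) - np.log(2)) < 0.1
        assert np.median(thetas) == pytest.approx(10.0, rel=0.25)
        assert np.mean(sigmas) == pytest.approx(0.4, rel=0.30)

    def test_batch_matches_single_gene_fits(self):
        rng = np.random.default_rng(6)
        cond = np.r_[np.zeros(5), np.ones(5)]
        Y = _nb(rng, np.exp(rng.uniform(3, 6, (8, 1))) * np.ones(10), 6.0)
        groups = [f"s{j}" for j in range(10)]
        batch = fit_matrix(Y.astype(float), cond, groups=groups)
        for i in range(8):
            single = NBGLMM(Y[i], cond, groups=groups).fit()
            np.testing.assert_allclose(batch[i, 0:2], single.params, rtol=1e-12)

    def test_failure_is_flagged_not_raised(self):
        # a gene with one condition entirely zero still returns a result
        cond = np.r_[np.zeros(4), np.ones(4)]
        y = np.array([0, 0, 0, 0, 9, 11, 10, 12], dtype=float)
        f = fit_nb_glmm(y, cond)
        assert np.isfinite(f.params[0]) or not f.converged


class TestWald:
    def _fit(self, beta, se):
        return NBGLMMResults(
            params=np.array([0.0, beta]),
            bse=np.array([1.0, se]),
            theta=1.0, sigma2=0.0, llf=0.0,
            converged=True, boundary=False, n_iter=1,
        )

    def test_zero_coefficient_gives_p_one(self):
        stat, p = wald_test(self._fit(0.0, 1.0), df=np.inf)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_critical_value_under_normal_reference(self):
        _, p = wald_test(self._fit(1.959964, 1.0), df=np.inf)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_symmetry(self):
        _, p_pos = wald_test(self._fit(2.0, 1.0), df=np.inf)
        _, p_neg = wald_test(self._fit(-2.0, 1.0), df=np.inf)
        assert p_pos == p_neg

    def test_t_reference_is_wider_than_normal(self):
        fit = self._fit(2.0, 1.0)
        fit.df_resid = 10
        _, p_t = wald_test(fit)
        _, p_z = wald_test(fit, df=np.inf)
        assert p_t > p_z

    def test_non_converged_fit_gives_na(self):
        fit = self._fit(1.0, 1.0)
        fit.converged = False
        stat, p = wald_test(fit)
        assert np.isnan(stat) and np.isnan(p)
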