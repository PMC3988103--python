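"""GLS likelihood core: estimator identities, lambda ML, LRTs, Type-I ANOVA."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal

from scorpallo import (
    ModelSpec,
    balanced_tree,
    fit_model,
    gls_profile_fit,
    lambda_transform,
    lrt_lambda,
    optimize_lambda,
    parse_newick,
    sequential_anova,
    vcv_from_tree,
)
from scorpallo.errors import NumericalError, TraitDataError
from scorpallo.pgls import profile_loglik
from scorpallo.synthetic_data import SimulationConfig, simulate_traits


def random_instance(rng, V, k=2):
    n = V.matrix.shape[0]
    X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
    beta = rng.standard_normal(k)
    L = np.linalg.cholesky(lambda_transform(V, rng.uniform()).matrix)
    y = X @ beta + 0.3 * (L @ rng.standard_normal(n))
    return y, X


class TestModelSpec:
    def test_formula_parsing(self):
        spec = ModelSpec.from_formula("ltm ~ lbm + pol")
        assert spec.response == "ltm" and spec.predictors == ("lbm", "pol")
        assert ModelSpec.from_formula("lsl ~ 1").predictors == ()
        assert ModelSpec.from_formula("lsv ~ lbm").label == "lsv ~ lbm"

    @pytest.mark.parametrize("bad", ["ltm", "~ lbm", "ltm ~", "ltm ~ ltm"])
    def test_malformed_formulas(self, bad):
        with pytest.raises(TraitDataError):
            ModelSpec.from_formula(bad)


class TestGLSProfileFit:
    def test_identity_covariance_equals_ols(self, rng):
        n = 12
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        beta, sigma2, ll = gls_profile_fit(y, X, np.eye(n))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(beta, ols.params)
        assert sigma2 == pytest.approx(float(ols.resid @ ols.resid) / n)
        assert ll == pytest.approx(float(ols.llf))

    def test_noiseless_data_flagged(self, vbase, rng):
        n = vbase.matrix.shape[0]
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        c = np.array([1.0, -2.0])
        with pytest.warns(UserWarning, match="zero"):
            beta, sigma2, ll = gls_profile_fit(X @ c, X, vbase)
        assert np.allclose(beta, c)
        assert sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_loglik_equals_mvn_density(self, vbase, rng):
        # the profiled Gaussian log-likelihood must equal the MVN log-density
        # evaluated at the fitted parameters
        for _ in range(10):
            y, X = random_instance(rng, vbase)
            lam = rng.uniform()
            V = lambda_transform(vbase, lam)
            beta, sigma2, ll = gls_profile_fit(y, X, V)
            oracle = multivariate_normal.logpdf(y, mean=X @ beta, cov=sigma2 * V.matrix)
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_singular_covariance_raises(self):
        with pytest.raises(NumericalError, match="cond"):
            gls_profile_fit(np.ones(3), np.ones((3, 1)), np.ones((3, 3)))


class TestOptimizeLambda:
    def test_matches_fine_grid(self, vbase, rng):
        grid = np.linspace(1e-4, 0.9999, 1000)
        for _ in range(5):
            y, X = random_instance(rng, vbase)
            fit = optimize_lambda(y, X, vbase)
            values = [profile_loglik(l, y, X, vbase) for l in grid]
            best = grid[int(np.argmax(values))]
            assert abs(fit.lambda_hat - best) < 0.01 or fit.loglik >= max(values) - 1e-9

    def test_never_below_coarse_anchor_points(self, vbase, rng):
        for _ in range(5):
            y, X = random_instance(rng, vbase)
            fit = optimize_lambda(y, X, vbase)
            anchors = [profile_loglik(l, y, X, vbase) for l in (1e-4, 0.5, 0.9999)]
            assert fit.loglik >= max(anchors) - 1e-9

    def test_recovers_independence_regime(self):
        # data simulated without phylogenetic signal: lambda-hat stays low
        phy = balanced_tree(16)
        cfg = SimulationConfig(
            tree=phy, X=np.ones((16, 1)), beta=[0.0], sigma2=1.0, lam=0.0,
            seed=7, replicates=40,
        )
        Y = simulate_traits(cfg)
        V = vcv_from_tree(phy)
        lams = [optimize_lambda(y, np.ones((16, 1)), V).lambda_hat for y in Y]
        assert np.median(lams) < 0.3


class TestLambdaLRT:
    def test_boundary_identity_and_refit_oracle(self, vbase, rng):
        for _ in range(5):
            y, X = random_instance(rng, vbase)
            fit = optimize_lambda(y, X, vbase)
            lrt = lrt_lambda(fit, y, X, vbase)
            assert lrt.statistic_vs_0 >= 0 and lrt.statistic_vs_1 >= 0
            assert 0 <= lrt.p_vs_0 <= 1 and 0 <= lrt.p_vs_1 <= 1
            # refit oracle: statistic equals twice the drop to a fixed-lambda fit
            ll0 = gls_profile_fit(y, X, lambda_transform(vbase, 0.0))[2]
            assert lrt.statistic_vs_0 == pytest.approx(
                max(0.0, 2 * (fit.loglik - ll0)), abs=1e-10
            )
            if fit.lambda_hat <= 1e-4:
                assert lrt.statistic_vs_0 == pytest.approx(0.0, abs=1e-6)
                assert lrt.p_vs_0 == pytest.approx(1.0, abs=1e-3)


class TestSequentialAnova:
    def test_single_predictor_matches_ols_anova(self, rng):
        # lambda=0 on an ultrametric tree whitens by a scalar: classic ANOVA
        star = parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")
        V0 = lambda_transform(vcv_from_tree(star), 0.0)
        x = rng.standard_normal(8)
        y = 1.0 + 0.8 * x + 0.3 * rng.standard_normal(8)
        X = np.column_stack([np.ones(8), x])
        term = sequential_anova(y, X, V0, ["x"])[0]
        ols = sm.OLS(y, X).fit()
        # textbook F for a single regressor equals its squared t statistic
        assert term.F == pytest.approx(float(ols.tvalues[1] ** 2), rel=1e-10)
        assert term.p == pytest.approx(float(ols.pvalues[1]), rel=1e-10)

    def test_decomposition_identity(self, vbase, rng):
        y, X = random_instance(rng, vbase, k=3)
        V = lambda_transform(vbase, 0.37)
        terms = sequential_anova(y, X, V, ["a", "b"])
        L = np.linalg.cholesky(V.matrix)
        z = np.linalg.solve(L, y)
        Z = np.linalg.solve(L, X)
        resid_int = z - Z[:, :1] @ np.linalg.lstsq(Z[:, :1], z, rcond=None)[0]
        resid_full = z - Z @ np.linalg.lstsq(Z, z, rcond=None)[0]
        total_after_intercept = float(resid_int @ resid_int)
        assert sum(t.ss for t in terms) + float(resid_full @ resid_full) == pytest.approx(
            total_after_intercept, rel=1e-10
        )

    def test_orthogonal_predictors_order_invariant(self, rng):
        star = parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")
        V0 = lambda_transform(vcv_from_tree(star), 0.0)
        a = rng.standard_normal(8)
        a -= a.mean()
        b = rng.standard_normal(8)
        b -= b.mean()
        b -= (b @ a) / (a @ a) * a  # orthogonalize against a (and intercept)
        y = 0.5 + a - 2 * b + 0.1 * rng.standard_normal(8)
        f_ab = sequential_anova(y, np.column_stack([np.ones(8), a, b]), V0, ["a", "b"])
        f_ba = sequential_anova(y, np.column_stack([np.ones(8), b, a]), V0, ["b", "a"])
        assert f_ab[0].F == pytest.approx(f_ba[1].F, rel=1e-9)
        assert f_ab[1].F == pytest.approx(f_ba[0].F, rel=1e-9)

    def test_no_residual_df_errors(self, rng):
        with pytest.raises(NumericalError):
            sequential_anova(np.ones(3), np.eye(3), np.eye(3), ["a", "b"])


class TestOLSEquivalenceLimits:
    def test_star_tree_lambda_one_and_ultrametric_lambda_zero(self, rng):
        star = parse_newick("(A:2,B:2,C:2,D:2,E:2,F:2);")
        V = vcv_from_tree(star)
        X = np.column_stack([np.ones(6), rng.standard_normal(6)])
        y = rng.standard_normal(6)
        ols = sm.OLS(y, X).fit()
        for lam in (1.0, 0.0):
            beta, _, _ = gls_profile_fit(y, X, lambda_transform(V, lam))
            assert np.allclose(beta, ols.params)

    def test_whitened_residuals_orthogonal_to_design(self, vbase, rng):
        y, X = random_instance(rng, vbase, k=3)
        fit = optimize_lambda(y, X, vbase)
        Vl = lambda_transform(vbase, fit.lambda_hat).matrix
        L = np.linalg.cholesky(Vl)
        ez = np.linalg.solve(L, y - X @ fit.beta)
        Z = np.linalg.solve(L, X)
        assert np.max(np.abs(Z.T @ ez)) < 1e-8


class TestParameterRecovery:
    def test_beta_unbiased_under_the_generative_model(self):
        # beta = (-2.1, 0.25), sigma2 = 0.05, lambda = 0.5 on a 64-tip tree
        phy = balanced_tree(64)
        n = 64
        rng = np.random.default_rng(11)
        x = rng.uniform(1.0, 4.0, size=n)
        X = np.column_stack([np.ones(n), x])
        beta_true = np.array([-2.1, 0.25])
        cfg = SimulationConfig(
            tree=phy, X=X, beta=beta_true, sigma2=0.05, lam=0.5, seed=303,
            replicates=500,
        )
        Y = simulate_traits(cfg)
        V = vcv_from_tree(phy)
        betas = np.array([optimize_lambda(y, X, V).beta for y in Y])
        mean_b = betas.mean(axis=0)
        mc_se = betas.std(axis=0, ddof=1) / np.sqrt(len(Y))
        assert np.all(np.abs(mean_b - beta_true) < 2 * mc_se + 1e-3)


class TestFitModel:
    def test_null_model_intercept_is_gls_weighted_mean(self, table1, vbase):
        fit0 = fit_model(ModelSpec("ltm"), table1, vbase, lam=0.0)
        # lambda = 0 on the (non-ultrametric) cladogram weights by 1/depth
        d = np.diag(vbase.matrix)
        y = table1.reordered(vbase.tip_order).analysis_matrix(["ltm"])[:, 0]
        assert fit0.coef("intercept") == pytest.approx(np.sum(y / d) / np.sum(1 / d))

    def test_positive_polyandry_slope_on_study_data(self, table1, vbase):
        fit = fit_model(ModelSpec("ltm", ("pol",)), table1, vbase)
        assert fit.coef("pol") > 0
        assert fit.lrt is not None
        assert fit.anova[0].F > 0
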