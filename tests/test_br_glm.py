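"""Bias-reduced binary GLM: oracles, separation behaviour, inference."""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit

from wmhmap import br_glm


def _jeffreys_logit_optimum(X, y):
    """Independent oracle: maximise the Jeffreys-penalised logistic loglik."""
    def neg_penalised(beta):
        eta = X @ beta
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        mu = expit(eta)
        W = X.T @ (X * (mu * (1 - mu))[:, None])
        sign, logdet = np.linalg.slogdet(W)
        if sign <= 0:
            return np.inf
        return -(ll + 0.5 * logdet)
    res = optimize.minimize(neg_penalised, np.zeros(X.shape[1]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20_000})
    return res.x


class TestBrOracles:
    def test_intercept_only_closed_form(self):
        """Mean-BR logistic intercept equals logit((k + 1/2)/(n + 1))."""
        X = np.ones((10, 1))
        y = np.r_[np.ones(2), np.zeros(8)]
        fit = br_glm.fit_binary_glm(br_glm.BinaryDesign(X=X, y=y, link="logit"),
                                    estimator="BR")
        assert fit.converged
        assert fit.estimates[0] == pytest.approx(np.log(2.5 / 8.5), abs=1e-8)
        # independent check: solve the adjusted score equation numerically
        def adj_score(b):
            mu = expit(b)
            h = 1.0 / 10  # balanced leverages for intercept-only
            return np.sum(y - mu + h * (0.5 - mu))
        root = optimize.brentq(adj_score, -10, 10)
        assert fit.estimates[0] == pytest.approx(root, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_logit_br_equals_jeffreys_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(15, 30)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(X @ np.array([-0.3, 1.0]))).astype(float)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        fit = br_glm.fit_binary_glm(br_glm.BinaryDesign(X=X, y=y, link="logit"),
                                    estimator="BR")
        oracle = _jeffreys_logit_optimum(X, y)
        assert np.allclose(fit.estimates, oracle, atol=1e-5)

    def test_ml_matches_generic_newton_on_overlapping_data(self):
        rng = np.random.default_rng(5)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(X @ np.array([0.2, 0.7]))).astype(float)
        fit = br_glm.fit_binary_glm(br_glm.BinaryDesign(X=X, y=y, link="logit"),
                                    estimator="ML")
        def negll(beta):
            eta = X @ beta
            return -np.sum(y * eta - np.logaddexp(0.0, eta))
        res = optimize.minimize(negll, np.zeros(2), method="BFGS",
                                options={"gtol": 1e-12})
        assert fit.converged
        assert np.allclose(fit.estimates, res.x, atol=1e-8)


class TestSeparation:
    def test_complete_separation_toy(self):
        """x = (-2,-1,1,2), y = (0,0,1,1): ML diverges, BR stays finite."""
        X = np.column_stack([np.ones(4), [-2.0, -1.0, 1.0, 2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        d = br_glm.BinaryDesign(X=X, y=y, link="logit")
        ml = br_glm.fit_binary_glm(d, estimator="ML")
        br = br_glm.fit_binary_glm(d, estimator="BR")
        assert not ml.converged
        assert br.converged and np.all(np.isfinite(br.estimates))
        assert br.separation_flag

    def test_probit_symmetry_gives_zero_intercept(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        X = np.column_stack([np.ones(6), x])
        y = (x > 0).astype(float)
        fit = br_glm.fit_binary_glm(br_glm.BinaryDesign(X=X, y=y),
                                    estimator="BR")
        assert abs(fit.estimates[0]) < 1e-6
        assert np.isfinite(fit.estimates[1])

    def test_check_separation_examples(self):
        thresholded = br_glm.BinaryDesign(
            X=np.column_stack([np.ones(6), [1, 2, 3, 4, 5, 6.0]]),
            y=np.array([0, 0, 0, 1, 1, 1.0]))
        assert br_glm.check_separation_risk(thresholded)
        overlapping = br_glm.BinaryDesign(
            X=np.column_stack([np.ones(4), [0, 0, 1, 1.0]]),
            y=np.array([0, 1, 0, 1.0]))
        assert not br_glm.check_separation_risk(overlapping)

    def test_check_separation_against_brute_force(self):
        """Exact agreement with an extreme-ray search on p<=2, n<=8 designs."""
        def brute_force(X, y):
            sgn = np.where(y == 1, 1.0, -1.0)
            Xt = X * sgn[:, None]
            cands = []
            for xi in X:
                cands += [xi, -xi]
                if X.shape[1] == 2:
                    cands += [np.array([-xi[1], xi[0]]), np.array([xi[1], -xi[0]])]
            for b in cands:
                v = Xt @ b
                if np.all(v >= -1e-9) and np.any(v > 1e-9):
                    return True
            return False

        rng = np.random.default_rng(0)
        checked = 0
        while checked < 300:
            n = rng.integers(2, 9)
            p = rng.integers(1, 3)
            X = rng.standard_normal((n, p))
            if p == 2 and rng.random() < 0.5:
                X[:, 0] = 1.0
            y = (rng.random(n) < 0.5).astype(float)
            if len(np.unique(y)) < 2 or np.linalg.matrix_rank(X) < p:
                continue
            d = br_glm.BinaryDesign(X=X, y=y)
            assert br_glm.check_separation_risk(d) == brute_force(X, y)
            checked += 1


class TestInference:
    def test_wald_examples(self):
        fit = br_glm.FitResult(
            estimates=np.array([0.0, 1.96]), estimator="BR", link="probit",
            se=np.array([0.5, 1.0]), z=None, p_values=None, converged=True,
            n_iter=3, separation_flag=False, info_matrix=np.eye(2),
            hat_values=np.zeros(4))
        z, p, ci = br_glm.wald_inference(fit)
        assert z[0] == 0.0 and p[0] == 1.0
        assert p[1] == pytest.approx(0.05, abs=1e-3)
        assert np.allclose(ci[1], [1.96 - 1.96, 1.96 + 1.96])

    def test_wald_p_matches_normal_cdf_grid(self):
        zgrid = np.linspace(-4, 4, 33)
        fit = br_glm.FitResult(
            estimates=zgrid.copy(), estimator="BR", link="probit",
            se=np.ones_like(zgrid), z=None, p_values=None, converged=True,
            n_iter=1, separation_flag=False,
            info_matrix=np.eye(len(zgrid)), hat_values=np.zeros(1))
        _, p, _ = br_glm.wald_inference(fit)
        brute = np.array([2 * stats.norm.cdf(-abs(v)) for v in zgrid])
        assert np.allclose(p, brute, atol=1e-12)

    def test_singular_information_names_coefficient(self):
        fit = br_glm.FitResult(
            estimates=np.array([1.0, 2.0]), estimator="BR", link="probit",
            se=np.array([0.5, 0.0]), z=None, p_values=None, converged=True,
            n_iter=1, separation_flag=False, info_matrix=np.eye(2),
            hat_values=np.zeros(1))
        with pytest.raises(np.linalg.LinAlgError, match="coefficient 1"):
            br_glm.wald_inference(fit)


class TestProperties:
    def test_equivariance_under_column_scaling(self):
        rng = np.random.default_rng(9)
        n = 120
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(X @ np.array([0.3, 0.8]))).astype(float)
        base = br_glm.fit_binary_glm(br_glm.BinaryDesign(X=X, y=y, link="logit"),
                                     estimator="BR")
        for c in (2.0, -0.5, 10.0):
            Xc = X.copy()
            Xc[:, 1] *= c
            scaled = br_glm.fit_binary_glm(
                br_glm.BinaryDesign(X=Xc, y=y, link="logit"), estimator="BR")
            assert scaled.estimates[1] == pytest.approx(base.estimates[1] / c,
                                                        abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="0/1"):
            br_glm.BinaryDesign(X=np.ones((3, 1)), y=np.array([0, 1, 2.0]))
        with pytest.raises(ValueError, match="link"):
            br_glm.BinaryDesign(X=np.ones((3, 1)), y=np.zeros(3), link="cloglog")
        with pytest.raises(np.linalg.LinAlgError):
            br_glm.BinaryDesign(X=np.ones((4, 2)), y=np.array([0, 1, 0, 1.0]))
        with pytest.raises(ValueError, match="non-finite"):
            br_glm.BinaryDesign(X=np.array([[np.inf]]), y=np.array([1.0]))

    def test_max_iter_exceeded_reported(self):
        rng = np.random.default_rng(2)
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(X @ np.array([0.0, 0.5]))).astype(float)
        fit = br_glm.fit_binary_glm(br_glm.BinaryDesign(X=X, y=y, link="logit"),
                                    estimator="BR", max_iter=1)
        assert not fit.converged
        assert fit.n_iter == 1
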