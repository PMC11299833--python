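"""Unit tests for the pooled logistic mixed-model engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from fedglmm import glmm
from fedglmm.glmm import CohortData, FitOptions, WorkingState


def intercept_cohort(y):
    y = np.asarray(y, dtype=float)
    n = len(y)
    return CohortData(
        sample_ids=np.arange(n).astype(str),
        y=y,
        X=np.ones((n, 1)),
        V=np.eye(n),
    )


class TestWorkingUpdate:
    def test_null_point_case(self):
        data = intercept_cohort([1.0, 0.0])
        ws = glmm.logistic_working_update(np.zeros(1), np.zeros(2), data)
        assert np.allclose(ws.eta, 0.0)
        assert np.allclose(ws.pi, 0.5)
        assert np.allclose(ws.w, 0.25)
        # Ytilde = eta + (y - pi)/nu = +-2 at pi = 1/2
        assert np.allclose(ws.ytilde, [2.0, -2.0])

    def test_matches_scalar_recomputation(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        data = CohortData(
            sample_ids=np.arange(n).astype(str),
            y=rng.integers(0, 2, n).astype(float),
            X=X,
            V=np.eye(n),
        )
        alpha = rng.normal(size=2)
        b = rng.normal(size=n)
        ws = glmm.logistic_working_update(alpha, b, data)
        for i in range(n):  # independent scalar loop
            eta = X[i] @ alpha + b[i]
            pi = 1.0 / (1.0 + np.exp(-eta))
            assert ws.ytilde[i] == pytest.approx(eta + (data.y[i] - pi) / (pi * (1 - pi)))
            assert ws.w[i] == pytest.approx(pi * (1 - pi))

    def test_nonfinite_eta_names_sample(self):
        data = intercept_cohort([1.0, 0.0])
        with pytest.raises(FloatingPointError, match="index 1"):
            glmm.logistic_working_update(np.zeros(1), np.array([0.0, np.inf]), data)


class TestNewtonInit:
    def test_intercept_only_balanced(self):
        res = glmm.newton_init_alpha(intercept_cohort([0, 0, 1, 1]))
        assert res.converged
        assert res.alpha[0] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_closed_form(self):
        # the intercept-only MLE is logit of the outcome mean
        res = glmm.newton_init_alpha(intercept_cohort([1, 1, 1, 0]))
        assert res.alpha[0] == pytest.approx(logit(0.75), abs=1e-8)

    def test_matches_irls_oracle(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = (rng.random(n) < expit(X @ [0.2, -0.6, 0.4])).astype(float)
        data = CohortData(np.arange(n).astype(str), y, X, np.eye(n))
        res = glmm.newton_init_alpha(data)
        import statsmodels.api as sm

        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(res.alpha - ref.params)) < 1e-6


def make_ws(w):
    w = np.asarray(w, dtype=float)
    z = np.zeros_like(w)
    return WorkingState(eta=z, pi=z + 0.5, nu=w, w=w, ytilde=z, psi=z)


class TestSigmaAndGLS:
    def test_identity_limit(self):
        f = glmm.assemble_sigma(make_ws(np.ones(3)), 0.0, np.eye(3))
        assert np.allclose(f.sigma_inv, np.eye(3))

    def test_scalar_case(self):
        # Sigma = 1/0.25 + 0.5*1 = 4.5
        f = glmm.assemble_sigma(make_ws([0.25]), 0.5, np.eye(1))
        assert f.sigma_inv[0, 0] == pytest.approx(2.0 / 9.0)

    def test_inverse_identity_random_spd(self, rng):
        n = 30
        B = rng.normal(size=(n, n))
        V = B @ B.T / n + np.eye(n)
        w = rng.uniform(0.1, 0.25, n)
        f = glmm.assemble_sigma(make_ws(w), 0.7, V)
        sigma = np.diag(1.0 / w) + 0.7 * V
        assert np.allclose(f.sigma_inv @ sigma, np.eye(n), atol=1e-8)
        assert np.allclose(f.v_sigma_inv, V @ f.sigma_inv)

    def test_gls_mean_case(self):
        f = glmm.SigmaFactors(sigma_inv=np.eye(2))
        _, Xi, ah = glmm.gls_update_alpha(f, np.ones((2, 1)), np.array([1.0, 3.0]))
        assert Xi[0, 0] == pytest.approx(2.0)
        assert ah[0] == pytest.approx(2.0)

    def test_gls_weighted_mean(self):
        f = glmm.SigmaFactors(sigma_inv=np.diag([1.0, 3.0]))
        _, _, ah = glmm.gls_update_alpha(f, np.ones((2, 1)), np.array([0.0, 4.0]))
        assert ah[0] == pytest.approx(3.0)

    def test_gls_matches_normal_equations(self, rng):
        n, p = 25, 3
        B = rng.normal(size=(n, n))
        Si = B @ B.T / n + np.eye(n)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        yt = rng.normal(size=n)
        f = glmm.SigmaFactors(sigma_inv=Si)
        _, _, ah = glmm.gls_update_alpha(f, X, yt)
        ref = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ yt)
        assert np.allclose(ah, ref, atol=1e-10)


class TestRandomEffects:
    def test_tau_zero(self):
        b = glmm.update_random_effects(0.0, np.eye(2), np.ones(2), np.zeros(2))
        assert np.allclose(b, 0.0)

    def test_scalar_case(self):
        b = glmm.update_random_effects(
            1.0, 0.5 * np.eye(2), np.array([2.0, -2.0]), np.zeros(2)
        )
        assert np.allclose(b, [1.0, -1.0])

    def test_matches_elementwise(self, rng):
        n = 12
        M = rng.normal(size=(n, n))
        yt, psi = rng.normal(size=n), rng.normal(size=n)
        b = glmm.update_random_effects(0.7, M, yt, psi)
        ref = np.array([0.7 * sum(M[i, k] * (yt[k] - psi[k]) for k in range(n)) for i in range(n)])
        assert np.allclose(b, ref)


class TestProjection:
    def test_centering_projector(self):
        # tau=0, w=1, intercept-only: P = I - 11'/n
        n = 6
        f = glmm.assemble_sigma(make_ws(np.ones(n)), 0.0, np.eye(n))
        glmm.gls_update_alpha(f, np.ones((n, 1)), np.zeros(n))
        P = glmm.projection_matrix(f)
        assert np.allclose(P, np.eye(n) - np.ones((n, n)) / n, atol=1e-10)
        assert np.allclose(P @ np.ones(n), 0.0, atol=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_projector_identities(self, seed):
        """PX = 0 and P Sigma P = P on randomized inputs."""
        rng = np.random.default_rng(seed)
        n, p = 20, 3
        B = rng.normal(size=(n, n))
        V = B @ B.T / n + np.eye(n)
        w = rng.uniform(0.05, 0.25, n)
        tau = rng.uniform(0.0, 2.0)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        f = glmm.assemble_sigma(make_ws(w), tau, V)
        glmm.gls_update_alpha(f, X, rng.normal(size=n))
        P = glmm.projection_matrix(f)
        sigma = np.diag(1.0 / w) + tau * V
        scale = np.abs(P).max()
        assert np.abs(P @ X).max() <= 1e-6 * scale
        assert np.abs(P @ sigma @ P - P).max() <= 1e-6 * scale


class TestAiReml:
    def _setup(self, rng, n=24):
        B = rng.normal(size=(n, n))
        V = B @ B.T / n + np.eye(n)
        w = rng.uniform(0.1, 0.25, n)
        X = np.ones((n, 1))
        f = glmm.assemble_sigma(make_ws(w), 0.4, V)
        yt = rng.normal(size=n)
        glmm.gls_update_alpha(f, X, yt)
        P = glmm.projection_matrix(f)
        return P, V, yt

    def test_zero_score_is_fixed_point(self, rng):
        P, V, yt = self._setup(rng)
        # rescale Ytilde so the quadratic form equals tr(PV): score = 0
        q = yt @ (P @ (V @ (P @ yt)))
        yt_star = yt * np.sqrt(np.sum(P * V) / q)
        assert glmm.aireml_tau_step(P, V, yt_star, 0.4) == pytest.approx(0.4, abs=1e-12)

    def test_step_sign_follows_score(self, rng):
        """Quadratic form above tr(PV) raises tau; below lowers it."""
        P, V, yt = self._setup(rng)
        q = yt @ (P @ (V @ (P @ yt)))
        t = np.sum(P * V)
        up = yt * np.sqrt(1.5 * t / q)
        down = yt * np.sqrt(0.5 * t / q)
        assert glmm.aireml_tau_step(P, V, up, 0.4) > 0.4
        assert glmm.aireml_tau_step(P, V, down, 0.4) < 0.4

    def test_floor_applies(self, rng):
        P, V, yt = self._setup(rng)
        tau = glmm.aireml_tau_step(P, V, 0.0 * yt, 1e-9)
        assert tau >= glmm.TAU_FLOOR


class TestNullFitGlmLimit:
    def test_reduces_to_logistic_regression(self, rng):
        import statsmodels.api as sm

        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n)])
        y = (rng.random(n) < expit(X @ [0.3, -0.5, 0.8])).astype(float)
        data = CohortData(np.arange(n).astype(str), y, X, np.eye(n))
        m = glmm.fit_null_pooled(data, FitOptions(fix_tau=0.0))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert m.converged
        assert np.max(np.abs(m.alpha - ref.params)) < 1e-6
        # score test equals the textbook efficient-score statistic
        g = rng.normal(1.0, 0.5, size=n)
        row = glmm.score_test_chunk(g[None, :], m.P, m.ytilde)[0]
        pi = ref.fittedvalues
        W = pi * (1 - pi)
        T_ref = g @ (y - pi)
        var_ref = g @ (W * g) - (g * W) @ X @ np.linalg.solve(
            (X * W[:, None]).T @ X, X.T @ (W * g)
        )
        assert row.score_T == pytest.approx(T_ref, rel=1e-6)
        assert row.var_T == pytest.approx(var_ref, rel=1e-6)

    def test_mixed_fit_converges_on_family_cohort(self, small_cohort):
        m = glmm.fit_null_pooled(small_cohort)
        assert m.converged
        assert m.tau >= glmm.TAU_FLOOR
        # projector identities hold on the fitted model
        sigma = np.diag(1.0 / m.working.w) + m.tau * small_cohort.V
        P = m.P
        scale = np.abs(P).max()
        assert np.abs(P @ small_cohort.X).max() <= 1e-6 * scale
        assert np.abs(P @ sigma @ P - P).max() <= 1e-6 * scale


class TestScoreTest:
    def test_monomorphic_variant_degenerate(self, small_cohort):
        m = glmm.fit_null_pooled(small_cohort)
        g = np.full(small_cohort.n, 2.0)  # constant: Pg = 0 via the intercept
        row = glmm.score_test_chunk(g[None, :], m.P, m.ytilde)[0]
        assert row.var_T == pytest.approx(0.0, abs=1e-8)
        assert row.pval is None
        assert row.reason == "degenerate variance"

    def test_chi2_quantile(self):
        # T^2/var at the chi^2_1 95th percentile maps to p = 0.05
        rows = glmm.score_rows_from_stats(
            np.array([np.sqrt(3.841459 * 2.0)]), np.array([2.0]), ["s"]
        )
        assert rows[0].pval == pytest.approx(0.05, abs=1e-6)

    def test_invariant_to_adding_covariate_span(self, small_cohort, rng):
        """T is unchanged when a scaled column of X is added to the genotype."""
        m = glmm.fit_null_pooled(small_cohort)
        g = rng.uniform(0, 2, size=small_cohort.n)
        g2 = g + 3.7 * small_cohort.X[:, 1]
        r1 = glmm.score_test_chunk(g[None, :], m.P, m.ytilde)[0]
        r2 = glmm.score_test_chunk(g2[None, :], m.P, m.ytilde)[0]
        assert r1.score_T == pytest.approx(r2.score_T, rel=1e-6, abs=1e-8)
        assert r1.var_T == pytest.approx(r2.var_T, rel=1e-6, abs=1e-8)


class TestAlleleStats:
    def test_basic_af(self):
        af, keep, _ = glmm.allele_stats_and_filter([np.array([[0.0, 0.0, 1.0, 2.0]])])
        assert af[0] == pytest.approx(0.375)
        assert keep[0]

    def test_rare_variant_filtered(self):
        G = np.array([[0.0] * 99 + [1.0]])  # af = 0.005
        af, keep, _ = glmm.allele_stats_and_filter([G], maf_threshold=0.01)
        assert af[0] == pytest.approx(0.005)
        assert not keep[0]

    def test_missing_imputed_to_dosage_mean(self):
        G = np.array([[0.0, 2.0, np.nan]])
        af, keep, blocks = glmm.allele_stats_and_filter([G])
        assert af[0] == pytest.approx(0.5)
        assert blocks[0][0, 2] == pytest.approx(1.0)

    def test_all_missing_dropped(self):
        G = np.array([[np.nan, np.nan]])
        af, keep, _ = glmm.allele_stats_and_filter([G])
        assert not keep[0]

    def test_pooled_across_sites(self):
        af, keep, _ = glmm.allele_stats_and_filter(
            [np.array([[0.0, 0.0]]), np.array([[1.0, 2.0]])]
        )
        assert af[0] == pytest.approx(0.375)
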