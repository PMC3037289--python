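"""Cox partial likelihood, its gradient, thresholding, TGDR fitting and tuning."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from coexsurv import (
    SurvivalData,
    fit_tuned,
    gradient,
    log_partial_likelihood,
    modified_threshold_vector,
    tgdr_fit,
    threshold_vector,
    tune_cv,
)
from coexsurv.coxtgdr import _standardize
from conftest import exponential_survival


def naive_gradient(beta, Z, surv):
    """O(n^2) risk-set oracle, written independently of the package internals."""
    eta = Z @ beta
    g = np.zeros(Z.shape[1])
    for i in range(surv.n):
        if surv.status[i] == 1:
            risk = surv.time >= surv.time[i]
            w = np.exp(eta[risk])
            g += Z[i] - (w @ Z[risk]) / w.sum()
    return g


def naive_loglik(beta, Z, surv):
    eta = Z @ beta
    total = 0.0
    for i in range(surv.n):
        if surv.status[i] == 1:
            risk = surv.time >= surv.time[i]
            total += eta[i] - np.log(np.exp(eta[risk]).sum())
    return total


@pytest.fixture
def cox_instance(rng):
    n, p = 40, 4
    Z = rng.standard_normal((n, p))
    beta_true = np.array([0.8, -0.5, 0.0, 0.0])
    T = rng.exponential(np.exp(-(Z @ beta_true)))
    C = rng.exponential(2.0, n)
    surv = SurvivalData(np.minimum(T, C), (T <= C).astype(int))
    return Z, surv


class TestLogPartialLikelihood:
    def test_closed_form_at_zero(self, cox_instance):
        Z, surv = cox_instance
        expected = -sum(
            np.log((surv.time >= surv.time[i]).sum())
            for i in range(surv.n) if surv.status[i] == 1
        )
        assert log_partial_likelihood(np.zeros(4), Z, surv) == pytest.approx(expected)

    def test_two_subject_hand_value(self):
        surv = SurvivalData(np.array([1.0, 2.0]), np.array([1, 1]))
        Z = np.array([[1.0], [0.0]])
        # R(0) = -log 2 - log 1
        assert log_partial_likelihood(np.zeros(1), Z, surv) == pytest.approx(-np.log(2))

    def test_matches_naive_oracle_and_bounded_by_mle(self, cox_instance, rng):
        Z, surv = cox_instance
        for _ in range(3):
            b = rng.standard_normal(4) * 0.5
            assert log_partial_likelihood(b, Z, surv) == pytest.approx(
                naive_loglik(b, Z, surv)
            )
        df = pd.DataFrame(np.column_stack([Z, surv.time, surv.status]),
                          columns=["z1", "z2", "z3", "z4", "t", "e"])
        cph = CoxPHFitter().fit(df, "t", "e")
        assert log_partial_likelihood(b, Z, surv) <= cph.log_likelihood_ + 1e-8

    def test_overflow_guarded(self, cox_instance):
        Z, surv = cox_instance
        val = log_partial_likelihood(np.full(4, 300.0), Z, surv)
        assert np.isfinite(val)


class TestGradient:
    def test_two_subject_hand_value(self):
        surv = SurvivalData(np.array([1.0, 2.0]), np.array([1, 1]))
        Z = np.array([[1.0], [0.0]])
        # event 1: Z=1 minus risk-set mean 0.5; event 2: 0 - 0
        assert gradient(np.zeros(1), Z, surv)[0] == pytest.approx(0.5)

    def test_constant_column_has_zero_gradient(self, cox_instance):
        Z, surv = cox_instance
        Zc = Z.copy()
        Zc[:, 2] = 3.14
        assert gradient(np.zeros(4), Zc, surv)[2] == pytest.approx(0.0, abs=1e-10)

    def test_matches_finite_differences(self, cox_instance, rng):
        Z, surv = cox_instance
        beta = rng.standard_normal(4) * 0.4
        g = gradient(beta, Z, surv)
        h = 1e-6
        fd = np.array([
            (log_partial_likelihood(beta + h * e, Z, surv)
             - log_partial_likelihood(beta - h * e, Z, surv)) / (2 * h)
            for e in np.eye(4)
        ])
        np.testing.assert_allclose(g, fd, atol=1e-4)

    def test_matches_naive_risk_set_oracle_with_ties(self, rng):
        Z = rng.standard_normal((12, 3))
        t = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0, 6.0, 7.0])
        d = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 1, 0, 1])
        surv = SurvivalData(t, d)
        beta = rng.standard_normal(3) * 0.3
        np.testing.assert_allclose(
            gradient(beta, Z, surv), naive_gradient(beta, Z, surv), atol=1e-10
        )


class TestThresholding:
    @pytest.mark.parametrize(
        "g,tau,expected",
        [
            ([0.1, -0.2], 0.0, [True, True]),
            ([0.1, -0.2], 1.0, [False, True]),
            ([0.1, -0.2, 0.09], 0.5, [True, True, False]),
        ],
    )
    def test_plain_cases(self, g, tau, expected):
        np.testing.assert_array_equal(threshold_vector(np.array(g), tau), expected)

    def test_zero_gradient_gives_all_false(self):
        assert not threshold_vector(np.zeros(3), 0.0).any()

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            threshold_vector(np.ones(2), 1.5)

    def test_selected_product_pulls_in_parents(self):
        index = [(0, 1), (0, 2), (1, 2)]
        g = np.array([0.01, 0.02, 1.0])  # only the interaction passes tau=0.5
        f = modified_threshold_vector(g, 0.5, index)
        np.testing.assert_array_equal(f, [True, True, True])

    def test_reduces_to_plain_without_selected_products(self):
        index = [(0, 1), (0, 2), (1, 2)]
        g = np.array([1.0, 0.8, 0.01])
        np.testing.assert_array_equal(
            modified_threshold_vector(g, 0.5, index), threshold_vector(g, 0.5)
        )

    def test_matches_rule_enumeration_oracle(self, rng):
        P = 4
        index = [(0, j) for j in range(1, P + 1)] + [
            (i, j) for i in range(1, P + 1) for j in range(i, P + 1)
        ]
        for _ in range(20):
            g = rng.standard_normal(len(index))
            tau = float(rng.uniform(0, 1))
            f = modified_threshold_vector(g, tau, index)
            thr = tau * np.abs(g).max()
            for c, (i, j) in enumerate(index):
                if i >= 1:
                    assert f[c] == (abs(g[c]) >= thr)
                else:
                    parent = any(
                        abs(g[c2]) >= thr
                        for c2, (i2, j2) in enumerate(index)
                        if i2 >= 1 and j in (i2, j2)
                    )
                    assert f[c] == (abs(g[c]) >= thr or parent)


class TestTgdrFit:
    def test_zero_iterations_keeps_beta_zero(self, cox_instance):
        Z, surv = cox_instance
        fit = tgdr_fit(Z, surv, tau=0.5, K=0)
        np.testing.assert_array_equal(fit.beta, 0)

    def test_tau_zero_is_plain_gradient_ascent(self, cox_instance):
        Z, surv = cox_instance
        K, dnu = 25, 1e-3
        fit = tgdr_fit(Z, surv, tau=0.0, K=K, delta_nu=dnu)
        Zs, _, scale = _standardize(Z)
        beta = np.zeros(4)
        for _ in range(K):
            beta = beta + dnu * naive_gradient(beta, Zs, surv)
        np.testing.assert_allclose(fit.beta, beta / scale, atol=1e-10)

    def test_tau_zero_converges_to_reference_cox_fit(self, rng):
        n = 30
        Z = rng.standard_normal((n, 2))
        T = rng.exponential(np.exp(-(0.9 * Z[:, 0] - 0.6 * Z[:, 1])))
        C = rng.exponential(3.0, n)
        surv = SurvivalData(np.minimum(T, C), (T <= C).astype(int))
        fit = tgdr_fit(Z, surv, tau=0.0, K=120_000)
        df = pd.DataFrame(np.column_stack([Z, surv.time, surv.status]),
                          columns=["z1", "z2", "t", "e"])
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-2)

    def test_likelihood_monotone_over_iterations(self, cox_instance):
        Z, surv = cox_instance
        Zs, _, _ = _standardize(Z)
        beta = np.zeros(4)
        prev = log_partial_likelihood(beta, Zs, surv)
        for _ in range(400):
            g = gradient(beta, Zs, surv)
            beta = beta + 1e-3 * g * threshold_vector(g, 0.3)
            cur = log_partial_likelihood(beta, Zs, surv)
            assert cur >= prev - 1e-12
            prev = cur

    def test_tau_one_updates_only_argmax(self, cox_instance):
        Z, surv = cox_instance
        Zs, _, _ = _standardize(Z)
        beta = np.zeros(4)
        for _ in range(50):
            g = gradient(beta, Zs, surv)
            f = threshold_vector(g, 1.0)
            assert f.sum() == 1
            beta = beta + 1e-3 * g * f

    def test_heredity_holds_at_every_iteration(self, rng):
        n, P = 60, 3
        first = rng.standard_normal((n, P))
        index = [(0, j) for j in range(1, P + 1)] + [
            (i, j) for i in range(1, P + 1) for j in range(i, P + 1)
        ]
        Z = np.column_stack(
            [first[:, j - 1] for _, j in index[:P]]
            + [first[:, i - 1] * first[:, j - 1] for i, j in index[P:]]
        )
        T = rng.exponential(np.exp(-(first[:, 0] * first[:, 1])))
        C = rng.exponential(2.0, n)
        surv = SurvivalData(np.minimum(T, C), (T <= C).astype(int))
        Zs, _, _ = _standardize(Z)
        beta = np.zeros(len(index))
        for _ in range(300):
            g = gradient(beta, Zs, surv)
            f = modified_threshold_vector(g, 0.8, index)
            beta = beta + 1e-3 * g * f
            for c, (i, j) in enumerate(index):
                if i >= 1 and beta[c] != 0:
                    assert beta[index.index((0, i))] != 0
                    assert beta[index.index((0, j))] != 0

    def test_modified_requires_index(self, cox_instance):
        Z, surv = cox_instance
        with pytest.raises(ValueError):
            tgdr_fit(Z, surv, tau=0.5, K=1, variant="modified")


class TestTuneCv:
    def test_same_seed_reproduces_folds_and_optimum(self, cox_instance):
        Z, surv = cox_instance
        args = dict(V=3, tau_grid=(1.0, 0.5, 0.0), K_max=120, patience=60, seed=7)
        out1 = tune_cv(Z, surv, **args)
        out2 = tune_cv(Z, surv, **args)
        assert out1[:2] == out2[:2]
        assert out1[2].keys() == out2[2].keys()

    def test_pure_noise_keeps_model_near_null(self, rng):
        n = 60
        Z = rng.standard_normal((n, 8))
        surv = exponential_survival(n, rng)
        fit = fit_tuned(Z, surv, V=3, tau_grid=(1.0, 0.5, 0.0), K_max=300,
                        patience=100, seed=3)
        # on the standardized scale the tuned coefficients stay small
        assert np.abs(fit.beta * fit.scale).max() < 0.5

    def test_single_strong_feature_selected(self, rng):
        n = 80
        Z = rng.standard_normal((n, 6))
        T = rng.exponential(np.exp(-1.5 * Z[:, 2]))
        C = rng.exponential(np.median(T) * 2, n)
        surv = SurvivalData(np.minimum(T, C), (T <= C).astype(int))
        fit = fit_tuned(Z, surv, V=3, tau_grid=(1.0, 0.5), K_max=400,
                        patience=150, seed=5)
        assert fit.selected[2]
        assert abs(fit.beta[2] * fit.scale[2]) == np.abs(fit.beta * fit.scale).max()
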