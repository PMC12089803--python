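import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm
from sklearn.metrics import roc_auc_score

from intgen.association import (
    AssociationError,
    bonferroni_threshold,
    conditional_test,
    fit_logistic,
    interaction_test,
    logistic_irls,
    nagelkerke_r2,
    roc_auc,
    tetrachoric,
)


def _sim_logistic(rng, n=2_000, beta=0.7):
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    eta = -1.0 + beta * x + 0.3 * z
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return y, x, z


# --- IRLS vs statsmodels ------------------------------------------------------

def test_irls_matches_statsmodels(rng):
    y, x, z = _sim_logistic(rng)
    X = np.column_stack([np.ones(len(y)), x, z])
    fit = logistic_irls(X, y)
    sm_fit = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(fit["beta"], sm_fit.params, atol=1e-6)
    np.testing.assert_allclose(
        np.sqrt(np.diag(fit["cov"])), sm_fit.bse, rtol=1e-4
    )
    assert fit["loglik"] == pytest.approx(sm_fit.llf, abs=1e-6)


def test_fit_logistic_matches_statsmodels_full_report(rng):
    y, x, z = _sim_logistic(rng)
    res = fit_logistic(y, x, covariates=z.reshape(-1, 1))
    X = np.column_stack([np.ones(len(y)), x, z])
    sm_fit = sm.Logit(y, X).fit(disp=0)
    assert res.beta == pytest.approx(sm_fit.params[1], abs=1e-6)
    assert res.se == pytest.approx(sm_fit.bse[1], rel=1e-4)
    assert res.p == pytest.approx(sm_fit.pvalues[1], rel=1e-3)
    assert res.or_ == pytest.approx(np.exp(sm_fit.params[1]), rel=1e-5)


def test_fit_logistic_listwise_deletion(rng):
    y, x, z = _sim_logistic(rng, n=500)
    x_miss = x.copy()
    x_miss[:50] = np.nan
    res = fit_logistic(y, x_miss, covariates=z.reshape(-1, 1))
    ref = fit_logistic(y[50:], x[50:], covariates=z[50:].reshape(-1, 1))
    assert res.beta == pytest.approx(ref.beta, abs=1e-10)
    assert res.n_case + res.n_control == 450


def test_fit_logistic_degenerate_inputs_raise(rng):
    y = np.ones(100)
    with pytest.raises(AssociationError):
        fit_logistic(y, np.random.default_rng(0).standard_normal(100))
    y2 = (np.random.default_rng(0).random(100) < 0.5).astype(float)
    with pytest.raises(AssociationError):
        fit_logistic(y2, np.zeros(100))


def test_fit_logistic_flags_separation():
    x = np.concatenate([np.zeros(50), np.ones(50)])
    y = x.copy()
    res = fit_logistic(y, x)
    assert not res.converged
    assert res.note in ("separation", "non-convergence")
    assert np.isnan(res.beta)


def test_wald_null_calibration_quick(rng):
    rejections = 0
    for _ in range(200):
        x = rng.standard_normal(500)
        y = (rng.random(500) < 0.4).astype(float)
        res = fit_logistic(y, x)
        rejections += res.p < 0.05
    assert 0.01 <= rejections / 200 <= 0.10


# --- pseudo-R2 and AUC --------------------------------------------------------

def test_nagelkerke_bounds_and_null():
    assert nagelkerke_r2(-100.0, -100.0, 500) == pytest.approx(0.0)
    r2 = nagelkerke_r2(-80.0, -100.0, 500)
    assert 0 < r2 < 1
    with pytest.raises(AssociationError):
        nagelkerke_r2(-101.0, -100.0, 500)


def test_nagelkerke_increment_positive_for_informative_predictor(rng):
    y, x, z = _sim_logistic(rng)
    res = fit_logistic(y, x, covariates=z.reshape(-1, 1))
    assert res.r2_nagelkerke > 0
    assert res.r2_full == pytest.approx(res.r2_covariates + res.r2_nagelkerke)


def test_roc_auc_exact_enumeration(rng):
    for _ in range(10):
        n = int(rng.integers(10, 200))
        scores = rng.standard_normal(n)
        y = (rng.random(n) < 0.4).astype(int)
        if y.min() == y.max():
            continue
        cases = scores[y == 1]
        controls = scores[y == 0]
        wins = sum(
            1.0 if c > d else (0.5 if c == d else 0.0)
            for c, d in itertools.product(cases, controls)
        )
        expected = wins / (len(cases) * len(controls))
        assert roc_auc(scores, y) == pytest.approx(expected, abs=1e-12)


def test_roc_auc_single_class_raises():
    with pytest.raises(AssociationError):
        roc_auc(np.arange(5.0), np.ones(5))


# --- tetrachoric --------------------------------------------------------------

def _grid_mle(table):
    t = np.asarray(table, dtype=float)
    n = t.sum()
    h = norm.ppf((t[0, 0] + t[0, 1]) / n)
    k = norm.ppf((t[0, 0] + t[1, 0]) / n)

    def nll(rho):
        bvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        p11 = bvn.cdf([-h, -k])
        p10 = norm.sf(h) - p11
        p01 = norm.sf(k) - p11
        p00 = 1 - p11 - p10 - p01
        probs = np.clip([p00, p01, p10, p11], 1e-12, None)
        counts = [t[0, 0], t[0, 1], t[1, 0], t[1, 1]]
        return -sum(c * np.log(p) for c, p in zip(counts, probs))

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded")
    return res.x


def test_tetrachoric_matches_brute_force_mle():
    tables = [
        np.array([[400, 100], [100, 400]]),
        np.array([[300, 200], [150, 350]]),
        np.array([[120, 380], [310, 190]]),
    ]
    for t in tables:
        assert tetrachoric(t) == pytest.approx(_grid_mle(t), abs=1e-3)


def test_tetrachoric_recovers_latent_correlation(rng):
    rho = 0.6
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=50_000)
    x = (z[:, 0] > 0.5).astype(int)
    y = (z[:, 1] > -0.2).astype(int)
    table = np.zeros((2, 2))
    for i, j in itertools.product((0, 1), repeat=2):
        table[i, j] = np.sum((x == i) & (y == j))
    assert tetrachoric(table) == pytest.approx(rho, abs=0.02)


def test_tetrachoric_degenerate_tables():
    assert tetrachoric(np.array([[50, 0], [0, 50]])) == pytest.approx(0.9995)
    assert tetrachoric(np.array([[0, 50], [50, 0]])) == pytest.approx(-0.9995)
    with pytest.raises(AssociationError):
        tetrachoric(np.array([[0, 0], [10, 10]]))


# --- interaction / conditional -------------------------------------------------

def test_interaction_test_recovers_product_effect(rng):
    n = 30_000
    x1 = rng.standard_normal(n)
    x2 = (rng.random(n) < 0.3).astype(float)
    eta = -1.0 + 0.3 * x1 + 0.2 * x2 + 0.5 * x1 * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    res = interaction_test(y, x1, x2)
    assert res.beta == pytest.approx(0.5, abs=0.1)
    assert res.p < 1e-6


def test_interaction_constant_moderator_flagged(rng):
    y, x, _ = _sim_logistic(rng, n=500)
    res = interaction_test(y, x, np.zeros(500))
    assert not res.converged and "inestimable" in res.note


def test_conditional_test_attenuates_mediated_effect(rng):
    n = 40_000
    carrier = (rng.random(n) < 0.05).astype(float)
    mood = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 1.2 * carrier)))).astype(float)
    # anxiety depends on carrier only through mood
    anx = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 1.5 * mood)))).astype(float)
    marginal = fit_logistic(anx, carrier)
    conditional = conditional_test(anx, carrier, mood)
    assert abs(conditional.beta) < abs(marginal.beta)
    assert conditional.p > 1e-3  # no direct effect left


def test_conditional_test_degenerate_flagged(rng):
    y, x, _ = _sim_logistic(rng, n=500)
    res = conditional_test(y, x, y)
    assert not res.converged and "degenerate" in res.note


# --- multiple testing -----------------------------------------------------------

def test_bonferroni_threshold_values():
    assert bonferroni_threshold(0.05, 16) == pytest.approx(3.125e-3)
    assert bonferroni_threshold(0.05, 24) == pytest.approx(0.05 / 24)
    with pytest.raises(AssociationError):
        bonferroni_threshold(0.05, 0)
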