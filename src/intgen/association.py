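"""Regression-based association analyses and fit metrics.

Logistic models are fit by iteratively reweighted least squares with Wald
standard errors from the observed information; pseudo-variance-explained is
the Nagelkerke rescaling of the Cox–Snell likelihood-ratio R², reported as
the increment of the full (predictor + covariates) model over the
covariates-only model; discrimination is the ROC AUC of the full-model
fitted probabilities.  Tetrachoric correlation is the maximum-likelihood
latent correlation of a dichotomised bivariate normal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, ndtri
from scipy.stats import multivariate_normal, norm
from sklearn.metrics import roc_auc_score


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# logistic regression by IRLS
# ---------------------------------------------------------------------------

def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict:
    """Maximum-likelihood logistic fit.

    Iterates reweighted least squares until the deviance changes by less
    than ``tol``; returns coefficients, the Wald covariance (inverse observed
    information), the log-likelihood and convergence diagnostics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))  # column 0 assumed intercept
    dev_old = np.inf
    converged = False
    cov = np.full((p, p), np.nan)
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw
        try:
            beta_new = np.linalg.solve(H, Xw.T @ z)
        except np.linalg.LinAlgError:
            break
        beta = beta_new
        mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        if abs(dev - dev_old) < tol:
            converged = True
            break
        dev_old = dev
    mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = mu * (1 - mu)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        converged = False
    # runaway coefficients signal (quasi-)complete separation
    separated = bool(np.max(np.abs(beta)) > 50)
    return {
        "beta": beta,
        "cov": cov,
        "loglik": ll,
        "converged": converged and not separated,
        "separated": separated,
    }


def _loglik_intercept_only(y: np.ndarray) -> float:
    n1 = y.sum()
    n0 = len(y) - n1
    p = n1 / len(y)
    if p in (0.0, 1.0):
        return 0.0
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


@dataclass
class AssociationResult:
    """One predictor's effect on one outcome from a logistic model."""

    outcome: str
    predictor: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    r2_nagelkerke: float          # increment of full over covariates-only
    r2_full: float
    r2_covariates: float
    auc: float                    # full-model fitted probabilities
    auc_covariates: float
    n_case: int
    n_control: int
    converged: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci95_lo"], d["ci95_hi"] = d.pop("ci95")
        return d


def _flagged_result(outcome, predictor, n_case, n_control, note) -> AssociationResult:
    nan = float("nan")
    return AssociationResult(
        outcome, predictor, nan, nan, nan, (nan, nan), nan, nan, nan, nan,
        nan, nan, n_case, n_control, converged=False, note=note,
    )


def fit_logistic(
    y: np.ndarray,
    x: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    outcome: str = "outcome",
    predictor: str = "predictor",
) -> AssociationResult:
    """Logistic regression of a binary outcome on one predictor plus
    covariates; reports the predictor coefficient with Wald inference,
    Nagelkerke ΔR² and full-model AUC.

    Rows with any missing value are dropped (listwise deletion).  A constant
    predictor or single-class outcome raises; separation or non-convergence
    yields a flagged (non-silent) result.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    parts = [y, x]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(y):
            covariates = covariates.T
        parts.append(covariates)
    stacked = np.column_stack(parts)
    ok = ~np.isnan(stacked).any(axis=1)
    y, x = y[ok], x[ok]
    cov_mat = covariates[ok] if covariates is not None else np.empty((ok.sum(), 0))
    n_case = int(y.sum())
    n_control = int(len(y) - n_case)
    if n_case == 0 or n_control == 0:
        raise AssociationError("outcome has a single class after listwise deletion")
    if np.std(x) == 0:
        raise AssociationError("predictor has no variation")

    X_full = np.column_stack([np.ones(len(y)), x, cov_mat])
    X_cov = np.column_stack([np.ones(len(y)), cov_mat])
    fit_full = logistic_irls(X_full, y)
    fit_cov = logistic_irls(X_cov, y)
    if not fit_full["converged"]:
        note = "separation" if fit_full["separated"] else "non-convergence"
        return _flagged_result(outcome, predictor, n_case, n_control, note)

    beta = float(fit_full["beta"][1])
    se = float(np.sqrt(fit_full["cov"][1, 1]))
    z = beta / se
    p = 2.0 * norm.sf(abs(z))
    ll0 = _loglik_intercept_only(y)
    r2_full = nagelkerke_r2(fit_full["loglik"], ll0, len(y))
    r2_cov = nagelkerke_r2(fit_cov["loglik"], ll0, len(y))
    prob_full = expit(X_full @ fit_full["beta"])
    prob_cov = expit(X_cov @ fit_cov["beta"])
    with np.errstate(over="ignore"):  # an infinite CI bound is honest here
        ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci95=ci,
        p=float(p),
        r2_nagelkerke=r2_full - r2_cov,
        r2_full=r2_full,
        r2_covariates=r2_cov,
        auc=roc_auc(prob_full, y),
        auc_covariates=roc_auc(prob_cov, y) if cov_mat.shape[1] else 0.5,
        n_case=n_case,
        n_control=n_control,
    )


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------

def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's rescaled Cox–Snell pseudo-R²."""
    if n <= 0:
        raise AssociationError("n must be positive")
    if loglik_full < loglik_null - 1e-8:
        raise AssociationError("full-model likelihood below null likelihood")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    if max_cs <= 0:
        return 0.0
    return float(cox_snell / max_cs)


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC area: P(score_case > score_control) + half the tie probability."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise AssociationError("AUC needs both classes")
    return float(roc_auc_score(y, scores))


# ---------------------------------------------------------------------------
# tetrachoric correlation
# ---------------------------------------------------------------------------

def _bvn_orthant(h: float, k: float, rho: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation rho."""
    return float(
        multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([-h, -k])
    )


def tetrachoric(table: np.ndarray) -> float:
    """Maximum-likelihood latent correlation of a 2x2 table.

    ``table[i, j]`` counts observations with X=i, Y=j (i, j in {0, 1}).
    Thresholds are fixed at the probit of the margins; rho is found by 1-D
    likelihood maximisation.  Degenerate concordant/discordant tables return
    the near-boundary value ±0.9995.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise AssociationError("need a non-negative 2x2 count table")
    n = t.sum()
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise AssociationError("tetrachoric undefined for an empty margin")
    if t[0, 1] == 0 and t[1, 0] == 0:
        return 0.9995
    if t[0, 0] == 0 and t[1, 1] == 0:
        return -0.9995
    px = t[1].sum() / n
    py = t[:, 1].sum() / n
    h = ndtri(1.0 - px)
    k = ndtri(1.0 - py)

    def negloglik(rho: float) -> float:
        p11 = _bvn_orthant(h, k, rho)
        p1x = px
        p_1 = py
        p10 = max(p1x - p11, 1e-12)
        p01 = max(p_1 - p11, 1e-12)
        p00 = max(1.0 - p11 - p10 - p01, 1e-12)
        p11 = max(p11, 1e-12)
        return -(
            t[1, 1] * np.log(p11)
            + t[1, 0] * np.log(p10)
            + t[0, 1] * np.log(p01)
            + t[0, 0] * np.log(p00)
        )

    res = minimize_scalar(negloglik, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


# ---------------------------------------------------------------------------
# interaction and conditional models
# ---------------------------------------------------------------------------

def interaction_test(
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    outcome: str = "outcome",
    label: str = "x1*x2",
) -> AssociationResult:
    """Logistic model with main effects and the x1·x2 product; reports the
    product-term coefficient."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.nanstd(x2) == 0 or np.nanstd(x1) == 0:
        return _flagged_result(outcome, label, int(np.nansum(y)),
                               int(len(y) - np.nansum(y)), "interaction inestimable: constant main effect")
    extra = np.column_stack([x2, x1])
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(y):
            covariates = covariates.T
        extra = np.column_stack([extra, covariates])
    # the product term is the reported predictor; main effects ride as covariates
    return fit_logistic(y, x1 * x2, covariates=extra, outcome=outcome, predictor=label)


def conditional_test(
    y_anxiety: np.ndarray,
    pcnv: np.ndarray,
    mood_flag: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    outcome: str = "anxiety",
    predictor: str = "any_pcnv",
) -> AssociationResult:
    """Anxiety ~ carrier status + mood + covariates; reports the carrier
    coefficient, i.e. the association independent of mood disorder."""
    y = np.asarray(y_anxiety, dtype=float)
    mood = np.asarray(mood_flag, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(mood))
    if np.array_equal(y[ok], mood[ok]):
        return _flagged_result(outcome, predictor, int(np.nansum(y)),
                               int(ok.sum() - np.nansum(y)),
                               "degenerate: conditioning variable equals outcome")
    extra = mood.reshape(-1, 1)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(y):
            covariates = covariates.T
        extra = np.column_stack([extra, covariates])
    return fit_logistic(y, pcnv, covariates=extra, outcome=outcome,
                        predictor=predictor + "|mood")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise AssociationError("n_tests must be >= 1")
    return alpha / n_tests


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
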