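"""Weighted GLM / mixture-likelihood fitting kernels.

Small, fast IRLS and maximum-likelihood routines used throughout the
package: weighted logistic and Poisson regression, gamma regression with
log link (whose IRLS weights are constant, so it is iterated WLS), and
the two zero-inflated families used for event-days and payments.  All
routines accept continuous observation weights (prior/variance weights:
each observation's log-likelihood contribution is multiplied by w_i).

statsmodels provides unweighted or var_weighted versions of the plain
families and is used as a cross-check in the test suite; the
zero-inflated likelihoods with continuous weights are fit here directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special


class FitError(RuntimeError):
    """Raised when a likelihood optimization fails to converge."""


@dataclass
class GLMFit:
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    extra: dict | None = None  # family-specific parameters (pi, alpha, ...)


def _wls_solve(X: np.ndarray, z: np.ndarray, w: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    XtW = X.T * w
    A = XtW @ X
    if ridge:
        A = A + ridge * np.eye(A.shape[1])
    return np.linalg.solve(A, XtW @ z)


def logistic_loglik(X, y, beta, w) -> float:
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None,
                 ridge: float = 0.0, max_iter: int = 100, tol: float = 1e-10) -> GLMFit:
    """Weighted logistic regression by IRLS (optionally ridge-stabilized)."""
    n, p = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        W = np.maximum(w * mu * (1 - mu), 1e-12)
        z = eta + (y - mu) / np.maximum(mu * (1 - mu), 1e-12)
        beta = _wls_solve(X, z, W, ridge)
        ll = logistic_loglik(X, y, beta, w) - 0.5 * ridge * float(beta @ beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            return GLMFit(beta, logistic_loglik(X, y, beta, w), True, it)
        ll_old = ll
    return GLMFit(beta, logistic_loglik(X, y, beta, w), False, max_iter)


def fit_logistic_safe(X, y, w=None) -> GLMFit:
    """Logistic fit that falls back to a weak ridge under (near-)separation."""
    fit = fit_logistic(X, y, w)
    if fit.converged and np.all(np.isfinite(fit.beta)) and np.max(np.abs(fit.beta)) < 30:
        return fit
    import warnings
    warnings.warn("possible separation in logistic fit; refitting with ridge 1e-6")
    return fit_logistic(X, y, w, ridge=1e-6, max_iter=200)


def poisson_loglik(X, y, beta, w) -> float:
    eta = X @ beta
    return float(np.sum(w * (y * eta - np.exp(eta) - special.gammaln(y + 1))))


def fit_poisson(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None,
                max_iter: int = 100, tol: float = 1e-10) -> GLMFit:
    """Weighted Poisson regression (log link) by IRLS."""
    n, p = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    beta = np.zeros(p)
    beta[0] = np.log(max(np.average(y, weights=w), 1e-8))
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = np.maximum(w * mu, 1e-12)
        z = eta + (y - mu) / np.maximum(mu, 1e-12)
        beta = _wls_solve(X, z, W)
        ll = poisson_loglik(X, y, beta, w)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            return GLMFit(beta, ll, True, it)
        ll_old = ll
    return GLMFit(beta, ll_old, False, max_iter)


def gamma_loglik(X, y, beta, alpha, w) -> float:
    mu = np.exp(X @ beta)
    return float(np.sum(w * (alpha * (np.log(alpha) + np.log(y) - np.log(mu))
                             - alpha * y / mu - np.log(y) - special.gammaln(alpha))))


def fit_gamma_log(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None,
                  max_iter: int = 200, tol: float = 1e-10) -> GLMFit:
    """Weighted gamma regression with log link; shape by profile MLE.

    For the log link the IRLS working weights are the prior weights, so
    the mean fit is iterated WLS on z = eta + (y-mu)/mu; the score for
    beta does not involve the shape, so beta-hat then alpha-hat is the
    joint MLE.  Requires y > 0.
    """
    n, p = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma regression requires strictly positive responses")
    beta = np.zeros(p)
    beta[0] = np.log(np.average(y, weights=w))
    eta_old = X @ beta
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        z = np.clip(X @ beta, -30, 30) + (y - mu) / mu
        beta = _wls_solve(X, z, w)
        eta = X @ beta
        if np.max(np.abs(eta - eta_old)) < tol * (np.max(np.abs(eta_old)) + 1.0):
            converged = True
            break
        eta_old = eta
    mu = np.exp(np.clip(X @ beta, -30, 30))
    # profile MLE for alpha: solve d/dalpha = 0
    r = np.average(np.log(y / mu) - y / mu, weights=w)

    def score(la):
        a = np.exp(la)
        return np.log(a) + 1.0 - special.digamma(a) + r

    lo, hi = -10.0, 15.0
    if score(lo) * score(hi) > 0:
        alpha = np.exp(hi) if score(hi) > 0 else np.exp(lo)
    else:
        alpha = float(np.exp(optimize.brentq(score, lo, hi, xtol=1e-12)))
    ll = gamma_loglik(X, y, beta, alpha, w)
    return GLMFit(beta, ll, converged, it, extra={"alpha": alpha})


# ---------------------------------------------------------------- zero-inflated


def zip_loglik(X, y, gamma0, beta, w) -> float:
    pi = special.expit(gamma0)
    lam = np.exp(np.clip(X @ beta, -30, 30))
    zero = y == 0
    ll = np.empty_like(lam)
    ll[zero] = np.log(pi + (1 - pi) * np.exp(-lam[zero]) + 1e-300)
    yp = y[~zero]
    ll[~zero] = (np.log1p(-pi) + yp * np.log(lam[~zero]) - lam[~zero]
                 - special.gammaln(yp + 1))
    return float(np.sum(w * ll))


def fit_zip(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None,
            max_iter: int = 500, tol: float = 1e-8) -> GLMFit:
    """Weighted zero-inflated Poisson MLE (intercept-only mixing part).

    Mixture: P(0) = pi + (1-pi) e^{-lam}; P(y>0) = (1-pi) Pois(y; lam),
    lam = exp(X beta).  Fit by EM: E-step assigns each zero a structural-
    zero responsibility, M-step is a weighted Poisson IRLS; converges by
    relative log-likelihood change < tol.
    """
    n = len(y)
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if np.all(y == 0):
        raise FitError("degenerate outcome: all responses are zero")
    zero = y == 0
    # init: Poisson fit, excess zeros -> pi
    pois = fit_poisson(X, y, w)
    beta = pois.beta
    pz = float(np.sum(w * zero) / np.sum(w))
    pi = min(max(pz / 2, 1e-4), 0.95)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        lam = np.exp(np.clip(X @ beta, -30, 30))
        # E-step: responsibility that a zero is structural
        r = np.zeros(n)
        ez = np.exp(-lam[zero])
        r[zero] = pi / (pi + (1 - pi) * ez + 1e-300)
        # M-step
        pi = float(np.sum(w * r) / np.sum(w))
        pi = min(max(pi, 1e-8), 1 - 1e-8)
        wp = w * (1 - r)
        beta = fit_poisson(X, y, np.maximum(wp, 1e-12)).beta
        g0 = special.logit(pi)
        ll = zip_loglik(X, y, g0, beta, w)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            return GLMFit(beta, ll, True, it, extra={"pi": pi, "gamma0": g0})
        ll_old = ll
    raise FitError(f"ZIP fit did not converge in {max_iter} EM iterations "
                   f"(last loglik {ll_old:.6g})")


def fit_zigamma(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> GLMFit:
    """Weighted zero-inflated gamma MLE (intercept-only mixing part).

    Zeros can only arise from the point mass, so pi-hat is the weighted
    zero fraction and the gamma part is the weighted gamma GLM on the
    positive observations: the likelihood factorizes exactly.
    """
    n = len(y)
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    pos = y > 0
    if not pos.any():
        raise FitError("degenerate outcome: all responses are zero")
    pi = float(np.sum(w * ~pos) / np.sum(w))
    gfit = fit_gamma_log(X[pos], y[pos], w[pos])
    ll = (float(np.sum(w[~pos]) * np.log(pi + 1e-300)) if pi > 0 else 0.0) \
        + float(np.sum(w[pos]) * np.log1p(-pi)) \
        + gfit.loglik
    return GLMFit(gfit.beta, ll, gfit.converged, gfit.n_iter,
                  extra={"pi": pi, "alpha": gfit.extra["alpha"]})
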