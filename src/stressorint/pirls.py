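"""Penalized IRLS fitting of spline models with REML smoothness selection.

The engine fits ``g(mu) = X beta`` with quadratic penalties
``sum_j lambda_j beta' S_j beta``. Smoothing parameters are chosen by
minimizing a restricted-likelihood score: the exact Gaussian REML criterion
for gaussian models, and its standard Laplace/working-model approximation
(penalized deviance plus log-determinant terms) for the other families.

The coefficient covariance at the selected smoothness is the Bayesian
``phi (X'WX + S_lambda)^{-1}``. An "unconditional" variant additionally
propagates smoothing-parameter uncertainty with a first-order correction
``V + J V_rho J'``, where ``J = d beta / d rho`` (``rho = log lambda``) by
finite differences and ``V_rho`` is the inverse curvature of the REML score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .families import deviance, nb_loglik, resolve_link, variance_function

log = logging.getLogger(__name__)

_MAX_RHO = 18.0


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class PirlsFit:
    beta: np.ndarray
    mu: np.ndarray
    eta: np.ndarray
    weights: np.ndarray          # final IRLS working weights (incl. prior)
    deviance: float
    edf: float
    phi: float                   # dispersion used in the covariance
    penalty: np.ndarray          # assembled S_lambda
    lambdas: np.ndarray
    cov: np.ndarray              # conditional (Bayesian) covariance
    cov_unconditional: np.ndarray | None
    theta: float | None          # NB size, if applicable
    iterations: int


def _assemble_penalty(p: int, penalties, lambdas) -> np.ndarray:
    S = np.zeros((p, p))
    for (sl, Sj, _), lam in zip(penalties, lambdas):
        S[sl, sl] += lam * Sj
    return S


def _logdet_plus(S: np.ndarray) -> tuple[float, int]:
    """Log pseudo-determinant and rank of a PSD matrix."""
    try:
        ev = np.linalg.eigvalsh(S)
    except np.linalg.LinAlgError:
        ev = np.linalg.svd(S, compute_uv=False)
    tol = max(S.shape[0], 1) * np.finfo(float).eps * max(ev.max(initial=0.0), 1.0)
    pos = ev[ev > tol]
    return float(np.sum(np.log(pos))), len(pos)


def _irls(X, y, family, link, prior_weights, S, theta=None,
          max_iter=100, tol=1e-9):
    """Penalized IRLS at fixed penalty S; y on the mean scale."""
    n, p = X.shape
    w = np.asarray(prior_weights, float)
    V = variance_function(family, theta)
    # standard mean initialisation
    if family == "binomial":
        mu = (w * y + 0.5) / (w + 1.0)
    elif family in ("poisson", "negative_binomial"):
        mu = np.maximum(y, 0.0) + 0.1
    else:
        mu = y.astype(float).copy()
    eta = link.fun(mu)
    dev = deviance(family, y, mu, w, theta)
    trace = []
    beta = np.zeros(p)
    for it in range(max_iter):
        dmu = link.inverse_deriv(eta)
        dmu = np.where(np.abs(dmu) < 1e-10, 1e-10, dmu)
        var = np.maximum(V(mu), 1e-10)
        wk = w * dmu ** 2 / var
        z = eta + (y - mu) / dmu
        WX = X * wk[:, None]
        A = X.T @ WX + S
        try:
            new_beta = np.linalg.solve(A, WX.T @ z)
        except np.linalg.LinAlgError:
            new_beta = np.linalg.lstsq(A, WX.T @ z, rcond=None)[0]

        def _eval(b):
            e = X @ b
            m = link.inverse(e)
            if family == "binomial":
                m = np.clip(m, 1e-10, 1 - 1e-10)
            elif family in ("poisson", "negative_binomial"):
                m = np.maximum(m, 1e-10)
            return e, m, deviance(family, y, m, w, theta)

        eta_n, mu_n, new_dev = _eval(new_beta)
        # step halving keeps the penalized-deviance descent property
        step = 1.0
        while (not np.isfinite(new_dev + new_beta @ S @ new_beta)
               or new_dev + new_beta @ S @ new_beta
               > dev + beta @ S @ beta + 1e-8) and step > 1e-8 and it > 0:
            step /= 2.0
            new_beta = beta + step * (new_beta - beta)
            eta_n, mu_n, new_dev = _eval(new_beta)
        beta, eta, mu = new_beta, eta_n, mu_n
        trace.append(new_dev)
        if not np.isfinite(new_dev):
            raise ConvergenceError("IRLS produced non-finite deviance", trace)
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise ConvergenceError(
            f"penalized IRLS did not converge in {max_iter} iterations", trace)
    dmu = link.inverse_deriv(eta)
    var = np.maximum(V(mu), 1e-10)
    wk = w * dmu ** 2 / var
    return beta, mu, eta, wk, dev, it + 1


def _reml_score(X, y, family, link, prior_weights, penalties, rho, theta=None):
    """Negative restricted log-likelihood up to rho-independent constants."""
    n, p = X.shape
    lambdas = np.exp(np.clip(rho, -_MAX_RHO, _MAX_RHO))
    S = _assemble_penalty(p, penalties, lambdas)
    try:
        beta, mu, eta, wk, dev, _ = _irls(X, y, family, link, prior_weights,
                                          S, theta)
    except ConvergenceError:
        return np.inf
    pen = float(beta @ S @ beta)
    A = X.T @ (X * wk[:, None]) + S
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    logdet_S, rank_S = _logdet_plus(S)
    mp = p - rank_S  # null-space (unpenalized) dimension
    if family == "gaussian":
        phi = (dev + pen) / max(n - mp, 1)
        return (0.5 * (dev + pen) / phi + 0.5 * (n - mp) * np.log(2 * np.pi * phi)
                + 0.5 * logdet_A - 0.5 * logdet_S)
    return 0.5 * (dev + pen) + 0.5 * logdet_A - 0.5 * logdet_S


def fit_penalized(X, y, family, link_name, prior_weights, penalties,
                  theta=None, optimize_theta=False,
                  unconditional=True) -> PirlsFit:
    """Full fit: optimize smoothing parameters, then assemble covariances.

    ``penalties`` is a list of ``(slice, S_block, label)``; an empty list
    reduces the engine to an unpenalized GLM fit.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    link = resolve_link(family, link_name)
    w = np.ones(n) if prior_weights is None else np.asarray(prior_weights, float)

    if family == "negative_binomial" and theta is None:
        optimize_theta, theta = True, 1.0

    n_sp = len(penalties)
    rho = np.zeros(n_sp)
    for _outer in range(6 if optimize_theta else 1):
        if n_sp:
            res = optimize.minimize(
                lambda r: _reml_score(X, y, family, link, w, penalties, r, theta),
                rho, method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200 * n_sp})
            rho = np.clip(res.x, -_MAX_RHO, _MAX_RHO)
        lambdas = np.exp(rho)
        S = _assemble_penalty(p, penalties, lambdas)
        beta, mu, eta, wk, dev, iters = _irls(X, y, family, link, w, S, theta)
        if not optimize_theta:
            break
        new_theta = _profile_theta(y, mu, w, theta)
        if abs(np.log(new_theta) - np.log(theta)) < 1e-4:
            theta = new_theta
            break
        theta = new_theta

    A = X.T @ (X * wk[:, None]) + S
    Ainv = np.linalg.inv(A)
    F = Ainv @ (A - S)            # influence of unpenalized fit
    edf = float(np.trace(F))
    _, rank_S = _logdet_plus(S) if n_sp else (0.0, 0)
    if family == "gaussian":
        phi = dev / max(n - edf, 1.0)
    else:
        phi = 1.0
    cov = phi * Ainv
    cov = 0.5 * (cov + cov.T)

    cov_unc = None
    if n_sp and unconditional:
        cov_unc = _unconditional_cov(X, y, family, link, w, penalties, rho,
                                     theta, beta, cov)
    return PirlsFit(beta=beta, mu=mu, eta=eta, weights=wk, deviance=dev,
                    edf=edf, phi=phi, penalty=S, lambdas=np.exp(rho),
                    cov=cov, cov_unconditional=cov_unc, theta=theta,
                    iterations=iters)


def _profile_theta(y, mu, w, theta0: float) -> float:
    res = optimize.minimize_scalar(
        lambda lt: -nb_loglik(y, mu, np.exp(lt), w),
        bounds=(np.log(1e-3), np.log(1e6)), method="bounded",
        options={"xatol": 1e-6})
    return float(np.exp(res.x))


def _unconditional_cov(X, y, family, link, w, penalties, rho, theta,
                       beta, cov) -> np.ndarray:
    """First-order smoothing-uncertainty correction V + J V_rho J'."""
    p = X.shape[1]
    n_sp = len(rho)
    h = 0.5
    J = np.zeros((p, n_sp))
    score = lambda r: _reml_score(X, y, family, link, w, penalties, r, theta)
    betas_pm = {}
    try:
        for j in range(n_sp):
            cols = []
            for sgn in (+1, -1):
                r = rho.copy()
                r[j] += sgn * h
                S = _assemble_penalty(p, penalties, np.exp(np.clip(r, -_MAX_RHO, _MAX_RHO)))
                b, *_ = _irls(X, y, family, link, w, S, theta)
                cols.append(b)
                betas_pm[(j, sgn)] = r
            J[:, j] = (cols[0] - cols[1]) / (2 * h)
        # numerical curvature of the REML score at the optimum
        H = np.zeros((n_sp, n_sp))
        f0 = score(rho)
        for j in range(n_sp):
            rp, rm = rho.copy(), rho.copy()
            rp[j] += h
            rm[j] -= h
            H[j, j] = (score(rp) - 2 * f0 + score(rm)) / h ** 2
            for k in range(j + 1, n_sp):
                rpp, rpm, rmp, rmm = (rho.copy() for _ in range(4))
                rpp[[j, k]] += h
                rmm[[j, k]] -= h
                rpm[j] += h
                rpm[k] -= h
                rmp[j] -= h
                rmp[k] += h
                H[j, k] = H[k, j] = (score(rpp) - score(rpm) - score(rmp)
                                     + score(rmm)) / (4 * h ** 2)
        ev, U = np.linalg.eigh(H)
        ev_inv = np.where(ev > 1e-8, 1.0 / np.maximum(ev, 1e-8), 0.0)
        V_rho = (U * ev_inv) @ U.T
        corr = J @ V_rho @ J.T
        out = cov + 0.5 * (corr + corr.T)
        return 0.5 * (out + out.T)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:  # pragma: no cover
        warnings.warn("smoothing-uncertainty correction unavailable "
                      f"({exc}); falling back to the conditional covariance. "
                      "Intervals may under-cover.")
        log.warning("unconditional covariance fallback: %s", exc)
        return cov.copy()
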