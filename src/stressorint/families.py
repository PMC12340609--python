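"""Link functions and distribution families for the penalized regression engine.

Only what the in-package penalized IRLS fitter needs: the link and its
derivative, the variance function, the (unit) deviance, and the natural
support of the response. Parametric-only models are fitted through
statsmodels and do not use these classes directly, but share the family
and link names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

FAMILIES = ("gaussian", "poisson", "negative_binomial", "binomial", "beta")
LINKS = ("canonical", "identity", "log", "logit")

#: canonical link per family
CANONICAL = {
    "gaussian": "identity",
    "poisson": "log",
    "negative_binomial": "log",
    "binomial": "logit",
    "beta": "logit",
}

_EPS = 1e-12


@dataclass(frozen=True)
class Link:
    name: str
    fun: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    # d mu / d eta evaluated at eta
    inverse_deriv: Callable[[np.ndarray], np.ndarray]


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def _expit(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                        np.exp(x) / (1.0 + np.exp(x)))


LINK_FUNCTIONS = {
    "identity": Link("identity", lambda m: np.asarray(m, float),
                     lambda e: np.asarray(e, float),
                     lambda e: np.ones_like(np.asarray(e, float))),
    "log": Link("log", lambda m: np.log(m), lambda e: np.exp(e),
                lambda e: np.exp(e)),
    "logit": Link("logit", _logit, _expit,
                  lambda e: _expit(e) * (1.0 - _expit(e))),
}


def resolve_link(family: str, link: str) -> Link:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    name = CANONICAL[family] if link == "canonical" else link
    if name not in LINK_FUNCTIONS:
        raise ValueError(f"unknown link {link!r}; expected one of {LINKS}")
    return LINK_FUNCTIONS[name]


def variance_function(family: str, theta: float | None = None) -> Callable:
    """V(mu): the mean-variance relationship up to the dispersion phi."""
    if family == "gaussian":
        return lambda mu: np.ones_like(np.asarray(mu, float))
    if family == "poisson":
        return lambda mu: np.asarray(mu, float)
    if family == "negative_binomial":
        if theta is None or theta <= 0:
            raise ValueError("negative_binomial variance needs size theta > 0")
        return lambda mu: mu + mu ** 2 / theta
    if family == "binomial":
        return lambda mu: mu * (1.0 - mu)
    raise ValueError(f"no IRLS variance function for family {family!r}")


def deviance(family: str, y, mu, prior_weights, theta: float | None = None) -> float:
    """Total deviance; y and mu on the proportion scale for binomial."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    w = np.asarray(prior_weights, float)
    if family == "gaussian":
        d = (y - mu) ** 2
    elif family == "poisson":
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, _EPS) / mu), 0.0)
        d = 2.0 * (ylogy - (y - mu))
    elif family == "negative_binomial":
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, _EPS) / mu), 0.0)
        d = 2.0 * (ylogy - (y + theta) * np.log((y + theta) / (mu + theta)))
    elif family == "binomial":
        yl = np.where(y > 0, y * np.log(np.maximum(y, _EPS) / mu), 0.0)
        yl2 = np.where(y < 1, (1 - y) * np.log(np.maximum(1 - y, _EPS) / (1 - mu)), 0.0)
        d = 2.0 * (yl + yl2)
    else:
        raise ValueError(f"no deviance for family {family!r}")
    return float(np.sum(w * d))


def support_bounds(family: str) -> tuple[float, float]:
    """Natural limits of the response mean for the family."""
    if family == "gaussian":
        return (-np.inf, np.inf)
    if family in ("poisson", "negative_binomial"):
        return (0.0, np.inf)
    return (0.0, 1.0)  # binomial / beta proportions


def nb_loglik(y, mu, theta, prior_weights=None) -> float:
    """Negative-binomial (NB2) log-likelihood with size theta."""
    from scipy import special

    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    ll = (special.gammaln(y + theta) - special.gammaln(theta)
          - special.gammaln(y + 1.0)
          + theta * np.log(theta / (theta + mu))
          + y * np.log(mu / (theta + mu)))
    if prior_weights is not None:
        ll = np.asarray(prior_weights, float) * ll
    return float(np.sum(ll))
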