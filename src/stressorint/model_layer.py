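"""Fitting and abstraction of generalized regression models.

Downstream interaction inference only needs three things from a fitted
model: response-scale predictions at arbitrary predictor rows (optionally
under perturbed coefficient vectors), the coefficient vector, and its
covariance matrix. :class:`FittedModel` is that contract.

Parametric models (no smooth terms) are fitted through statsmodels
(GLM / negative-binomial ML / beta regression). Models containing smooth
terms are fitted with the in-package penalized-spline engine
(:mod:`stressorint.pirls`), which performs REML-type smoothness selection
and offers an "unconditional" covariance that propagates
smoothing-parameter uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DesignBuilder, Term, _is_numeric
from .families import CANONICAL, FAMILIES, resolve_link, support_bounds
from .pirls import ConvergenceError, fit_penalized

log = logging.getLogger(__name__)

__all__ = ["ModelSpec", "CovariateProfile", "FittedModel", "fit_model",
            "predict_mean", "coefficient_covariance", "likelihood_ratio_test",
            "ConvergenceError"]


@dataclass(frozen=True)
class ModelSpec:
    """Response, distributional assumption and systematic part of a model."""

    response: str
    terms: tuple[Term, ...]
    family: str = "gaussian"
    link: str = "canonical"
    trials: str | None = None

    def __post_init__(self):
        if not self.response:
            raise ValueError("response column must be named")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        resolve_link(self.family, self.link)  # validates the combination
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def link_name(self) -> str:
        return CANONICAL[self.family] if self.link == "canonical" else self.link


@dataclass(frozen=True)
class CovariateProfile:
    """How covariates are held fixed when predicting at stressor corners.

    ``observed`` evaluates at each observation's own covariates, ``mean``
    at numeric means and factor modes of the training data, and
    ``representative`` at user-supplied values.
    """

    mode: str = "observed"
    values: Mapping[str, object] | None = None

    def __post_init__(self):
        if self.mode not in ("observed", "mean", "representative"):
            raise ValueError(f"unknown profile mode {self.mode!r}")
        if self.mode == "representative" and not self.values:
            raise ValueError("representative profile requires values")


class FittedModel:
    """A fitted generalized regression model.

    Exposes response-scale predictions (including under externally supplied
    coefficient vectors, which is what the delta method and posterior
    simulation need), the coefficient covariance in conditional and
    unconditional variants, and the estimated dispersion.
    """

    def __init__(self, spec: ModelSpec, builder: DesignBuilder,
                 coefficients: np.ndarray, cov: np.ndarray,
                 dispersion: float, data: pd.DataFrame,
                 cov_unconditional: np.ndarray | None = None,
                 llf: float | None = None, edf: float | None = None,
                 converged: bool = True):
        self.spec = spec
        self.builder = builder
        self.coefficients = np.asarray(coefficients, float)
        self._cov = np.asarray(cov, float)
        self._cov_unc = (None if cov_unconditional is None
                         else np.asarray(cov_unconditional, float))
        self.dispersion = float(dispersion)
        self.data = data
        self.llf = llf
        self.edf = edf if edf is not None else float(len(self.coefficients))
        self.converged = converged
        self.coefficient_names = list(builder.column_names)
        self.fitted_means = self.predict_mean(data)
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self._cov.shape != (len(self.coefficients),) * 2:
            raise ValueError("covariance dimension mismatch")

    # -- predictions -----------------------------------------------------

    @property
    def family(self) -> str:
        return self.spec.family

    @property
    def link_name(self) -> str:
        return self.spec.link_name

    def design_matrix(self, rows: pd.DataFrame) -> np.ndarray:
        return self.builder.build(rows)

    def predict_mean(self, rows: pd.DataFrame,
                     coefficients: np.ndarray | None = None) -> np.ndarray:
        """Inverse-link-transformed linear predictor at ``rows``.

        ``coefficients`` may be a vector or a ``(p, d)`` matrix of d
        alternative coefficient vectors, in which case an ``(n, d)`` array
        of means is returned.
        """
        X = self.design_matrix(pd.DataFrame(rows))
        beta = self.coefficients if coefficients is None else np.asarray(coefficients)
        link = resolve_link(self.family, self.spec.link)
        return link.inverse(X @ beta)

    # -- covariance ------------------------------------------------------

    def covariance(self, unconditional: bool = False) -> np.ndarray:
        if not unconditional:
            return self._cov
        if not self.builder.has_smooths:
            return self._cov  # identical for purely parametric models
        if self._cov_unc is None:
            raise ValueError("unconditional covariance is undefined for this "
                             "model class")
        return self._cov_unc

    # -- tests -----------------------------------------------------------

    def wald_test(self, term_label: str,
                  unconditional: bool = False) -> tuple[float, float, float]:
        """Wald chi-square test that all coefficients of a term are zero.

        Returns ``(statistic, df, p_value)``; df is the coefficient count
        (a pseudoinverse is used if the covariance block is rank deficient).
        """
        from scipy import stats

        slices = self.builder.term_slices().get(term_label)
        if slices is None:
            raise KeyError(f"no term labelled {term_label!r}; have "
                           f"{sorted(self.builder.term_slices())}")
        idx = np.concatenate([np.arange(s.start, s.stop) for s in slices])
        b = self.coefficients[idx]
        V = self.covariance(unconditional)[np.ix_(idx, idx)]
        Vinv = np.linalg.pinv(V)
        stat = float(b @ Vinv @ b)
        df = float(np.linalg.matrix_rank(V))
        return stat, df, float(stats.chi2.sf(stat, df))

    def profile_row(self, profile: CovariateProfile,
                    exclude: Sequence[str] = ()) -> dict:
        """One row of covariate values under a mean/representative profile."""
        out: dict = {}
        for col in self.data.columns:
            if col in exclude or col == self.spec.response or col == self.spec.trials:
                continue
            if profile.mode == "representative" and col in profile.values:
                out[col] = profile.values[col]
            elif _is_numeric(self.data[col]):
                out[col] = float(self.data[col].mean())
            else:
                counts = self.data[col].value_counts()
                top = counts.max()
                modes = sorted(counts[counts == top].index.tolist())
                if len(modes) > 1:
                    log.info("mode tie for %r; using first sorted level %r",
                             col, modes[0])
                out[col] = modes[0]
        if profile.mode == "representative":
            missing = [c for c in out if c not in profile.values]
            if missing:
                raise ValueError("representative profile must supply a value "
                                 f"for every covariate; missing {missing!r}")
        return out


# ---------------------------------------------------------------------------


def _binomial_endog(data: pd.DataFrame, spec: ModelSpec):
    """Successes and trials from either a count or a proportion response."""
    y = data[spec.response].to_numpy(float)
    if spec.trials is not None:
        trials = data[spec.trials].to_numpy(float)
    else:
        trials = np.ones_like(y)
    if np.any(trials <= 0):
        raise ValueError("binomial trials must be positive")
    is_int = np.allclose(y, np.round(y))
    if is_int and np.any(y > 1):
        successes = y
    elif is_int and spec.trials is None:
        successes = y  # Bernoulli 0/1
    else:
        if np.any((y < 0) | (y > 1)):
            raise ValueError("binomial proportions must lie in [0, 1]")
        successes = y * trials
    if np.any(successes > trials + 1e-9) or np.any(successes < 0):
        raise ValueError("binomial successes must lie in [0, trials]")
    return successes, trials


def _validate_support(data: pd.DataFrame, spec: ModelSpec):
    y = data[spec.response].to_numpy(float)
    if spec.family in ("poisson", "negative_binomial"):
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError(f"{spec.family} family requires non-negative "
                             "integer counts")
    if spec.family == "beta":
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("beta family requires responses strictly in (0,1)")


_SM_LINKS = {"identity": sm.families.links.Identity,
             "log": sm.families.links.Log,
             "logit": sm.families.links.Logit}


def fit_model(data: pd.DataFrame, spec: ModelSpec,
              unconditional: bool = True) -> FittedModel:
    """Fit ``spec`` to ``data`` and return a :class:`FittedModel`.

    Smooth terms are fitted with penalized splines, with smoothing
    parameters selected by a restricted-likelihood criterion; the
    negative-binomial size parameter is estimated from the data.
    """
    data = pd.DataFrame(data).reset_index(drop=True)
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    _validate_support(data, spec)
    builder = DesignBuilder(spec.terms, data)
    if len(data) <= builder.n_coef and not builder.has_smooths:
        raise ValueError(f"need more rows ({len(data)}) than coefficients "
                         f"({builder.n_coef})")
    X = builder.build(data)

    if builder.has_smooths:
        return _fit_gam(data, spec, builder, X, unconditional)
    return _fit_parametric(data, spec, builder, X)


def _fit_gam(data, spec, builder, X, unconditional) -> FittedModel:
    if spec.family == "beta":
        raise ValueError("smooth terms are not supported for the beta family")
    link_name = spec.link_name
    if spec.family == "binomial":
        successes, trials = _binomial_endog(data, spec)
        y = successes / trials
        w = trials
    else:
        y = data[spec.response].to_numpy(float)
        w = None
    fit = fit_penalized(X, y, spec.family, link_name, w,
                        builder.penalty_matrices(),
                        unconditional=unconditional)
    dispersion = {"gaussian": fit.phi,
                  "negative_binomial": fit.theta or 1.0}.get(spec.family, 1.0)
    return FittedModel(spec, builder, fit.beta, fit.cov, dispersion, data,
                       cov_unconditional=fit.cov_unconditional,
                       edf=fit.edf, converged=True)


def _fit_parametric(data, spec, builder, X) -> FittedModel:
    link_name = spec.link_name
    fam = spec.family
    if fam == "negative_binomial":
        if link_name != "log":
            raise ValueError("negative_binomial supports the log link only")
        return _fit_negbin(data, spec, builder, X)
    if fam == "beta":
        if link_name != "logit":
            raise ValueError("beta family supports the logit link only")
        return _fit_beta(data, spec, builder, X)

    link = _SM_LINKS[link_name]()
    if fam == "gaussian":
        family = sm.families.Gaussian(link)
        endog = data[spec.response].to_numpy(float)
        model = sm.GLM(endog, X, family=family)
    elif fam == "poisson":
        family = sm.families.Poisson(link)
        endog = data[spec.response].to_numpy(float)
        model = sm.GLM(endog, X, family=family)
    else:  # binomial
        successes, trials = _binomial_endog(data, spec)
        family = sm.families.Binomial(link)
        model = sm.GLM(np.column_stack([successes, trials - successes]), X,
                       family=family)
    try:
        res = model.fit()
    except Exception as exc:  # statsmodels raises several convergence types
        raise ConvergenceError(f"GLM fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("GLM fit produced non-finite coefficients")
    dispersion = float(res.scale) if fam == "gaussian" else 1.0
    return FittedModel(spec, builder, res.params, res.cov_params(),
                       dispersion, data, llf=float(res.llf))


def _fit_negbin(data, spec, builder, X) -> FittedModel:
    from statsmodels.discrete.discrete_model import NegativeBinomial

    endog = data[spec.response].to_numpy(float)
    model = NegativeBinomial(endog, X, loglike_method="nb2")
    res = model.fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        res = model.fit(disp=0, method="nm", maxiter=5000, start_params=res.params)
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("negative-binomial ML did not converge",
                               trace=[res.mle_retvals])
    alpha = float(res.params[-1])
    alpha = max(alpha, 1e-8)
    theta = 1.0 / alpha
    p = X.shape[1]
    cov = np.asarray(res.cov_params())[:p, :p]
    return FittedModel(spec, builder, res.params[:p], cov, theta, data,
                       llf=float(res.llf))


def _fit_beta(data, spec, builder, X) -> FittedModel:
    from statsmodels.othermod.betareg import BetaModel

    endog = data[spec.response].to_numpy(float)
    res = BetaModel(endog, X).fit(disp=0)
    p = X.shape[1]
    precision = float(np.exp(res.params[-1]))
    cov = np.asarray(res.cov_params())[:p, :p]
    return FittedModel(spec, builder, res.params[:p], cov, precision, data,
                       llf=float(res.llf))


# -- free-function forms of the contract ------------------------------------


def predict_mean(model: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    return model.predict_mean(rows)


def coefficient_covariance(model: FittedModel,
                           unconditional: bool = False) -> np.ndarray:
    return model.covariance(unconditional)


def likelihood_ratio_test(full: FittedModel,
                          reduced: FittedModel) -> tuple[float, float, float]:
    """LR chi-square test of nested parametric models."""
    from scipy import stats

    if full.llf is None or reduced.llf is None:
        raise ValueError("likelihood-ratio test requires parametric fits with "
                         "stored log-likelihoods")
    stat = 2.0 * (full.llf - reduced.llf)
    df = len(full.coefficients) - len(reduced.coefficients)
    if df <= 0:
        raise ValueError("models are not nested in the expected direction")
    return float(stat), float(df), float(stats.chi2.sf(stat, df))


def family_support(model: FittedModel) -> tuple[float, float]:
    return support_bounds(model.family)
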