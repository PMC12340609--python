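"""Standard errors and confidence intervals for interaction estimates.

Three routes from the coefficient covariance to the uncertainty of a
nonlinear post-estimation quantity:

* **delta** — first-order propagation ``se = sqrt(g' V g)`` with ``g`` the
  numerical gradient of the estimator in the coefficients. Fast, but
  assumes local linearity; unreliable for the dominance estimator near
  points where the min switches branches.
* **kr** (Krinsky–Robb) — draw coefficient vectors from a multivariate
  normal centred at the fit with the selected covariance, evaluate the
  estimator per draw, and read se and percentile intervals off the draws.
  The default route, and the one the type-I-error protocol uses.
* **bootstrap** — case resampling (optionally stratified by treatment
  cell), refitting the model per replicate.

For smooth models the Krinsky–Robb default uses the unconditional
covariance so smoothing-parameter uncertainty is propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .interaction_estimators import (ContrastSpec, InteractionEstimate,
                                     average_interaction,
                                     average_interaction_function,
                                     observationwise_function)
from .model_layer import FittedModel, fit_model

log = logging.getLogger(__name__)

__all__ = ["UncertaintyMethod", "delta_se", "kr_interval",
           "bootstrap_interval", "significance", "estimate_with_uncertainty",
           "observationwise_with_uncertainty"]


@dataclass(frozen=True)
class UncertaintyMethod:
    kind: str = "kr"
    draws: int = 10_000
    replicates: int = 2_000
    level: float = 0.95
    seed: int = 0
    covariance_variant: str | None = None  # None = unconditional iff smooths

    def __post_init__(self):
        if self.kind not in ("delta", "kr", "bootstrap"):
            raise ValueError(f"unknown uncertainty method {self.kind!r}")
        if self.kind == "kr" and self.draws < 100:
            raise ValueError("kr needs at least 100 draws")
        if self.kind == "bootstrap" and self.replicates < 200:
            raise ValueError("bootstrap needs at least 200 replicates")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        if self.covariance_variant not in (None, "conditional", "unconditional"):
            raise ValueError("covariance_variant must be conditional, "
                             "unconditional, or None for the default")


def _select_cov(model: FittedModel, variant: str | None) -> np.ndarray:
    if variant is None:
        variant = "unconditional" if model.builder.has_smooths else "conditional"
    return model.covariance(unconditional=(variant == "unconditional"))


def delta_se(model: FittedModel, estimator, covariance_variant: str | None = None,
             null_model: str | None = None, rel_step: float = 1e-6) -> float:
    """Delta-method standard error of ``estimator(coefficients)``.

    The gradient is taken by central differences with a relative step.
    """
    if null_model == "DO":
        log.warning("delta-method standard errors are unreliable for the "
                    "dominance estimator near min-switch points; prefer kr")
    beta = model.coefficients
    p = len(beta)
    h = rel_step * np.maximum(np.abs(beta), 1.0)
    pert = np.tile(beta[:, None], (1, 2 * p))
    for j in range(p):
        pert[j, 2 * j] += h[j]
        pert[j, 2 * j + 1] -= h[j]
    vals = np.asarray(estimator(pert), float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("estimator non-finite at perturbed coefficients; "
                         "delta method unavailable")
    g = (vals[0::2] - vals[1::2]) / (2 * h)
    V = _select_cov(model, covariance_variant)
    var = float(g @ V @ g)
    return float(np.sqrt(max(var, 0.0)))


def _mvn_draws(beta: np.ndarray, V: np.ndarray, n: int,
               rng: np.random.Generator) -> np.ndarray:
    p = len(beta)
    jitter = 1e-12 * max(np.trace(V) / p, 1e-300)
    for _ in range(6):
        try:
            L = np.linalg.cholesky(V + jitter * np.eye(p))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:
        raise np.linalg.LinAlgError("covariance is not positive semi-definite")
    return beta[:, None] + L @ rng.standard_normal((p, n))


def kr_interval(model: FittedModel, estimator, method: UncertaintyMethod
                ) -> tuple[float, tuple[float, float]]:
    """Krinsky–Robb se and percentile interval for ``estimator``.

    Draws failing the estimator's domain (NaN) are discarded and counted;
    more than 1% discarded aborts with a diagnostic.
    """
    rng = np.random.default_rng(method.seed)
    V = _select_cov(model, method.covariance_variant)
    draws = _mvn_draws(model.coefficients, V, method.draws, rng)
    vals = np.asarray(estimator(draws), float)
    ok = np.isfinite(vals)
    discarded = int((~ok).sum())
    if discarded > 0.01 * method.draws:
        raise RuntimeError(
            f"{discarded}/{method.draws} posterior draws fell outside the "
            "estimator's domain (e.g. non-positive MU corner predictions); "
            "the sampling distribution is not interpretable here")
    vals = vals[ok]
    alpha = 1.0 - method.level
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(np.std(vals, ddof=1)), (float(lo), float(hi))


def bootstrap_interval(data: pd.DataFrame, spec, null_model: str,
                       contrast: ContrastSpec, method: UncertaintyMethod,
                       strata: str | list[str] | None = None
                       ) -> tuple[float, tuple[float, float]]:
    """Case-resampling bootstrap se and percentile interval.

    Rows are resampled with replacement, within strata when ``strata``
    names treatment-cell columns (recommended for factorial designs), the
    model refitted and the average interaction recomputed per replicate.
    """
    data = pd.DataFrame(data).reset_index(drop=True)
    if strata is not None:
        cols = [strata] if isinstance(strata, str) else list(strata)
        groups = [idx.to_numpy() for _, idx in data.groupby(cols).groups.items()]
    else:
        groups = [np.arange(len(data))]
    vals, failures = [], 0
    for rep in range(method.replicates):
        rng = np.random.default_rng([method.seed, rep])
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True)
                              for g in groups])
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            refit = fit_model(sample, spec)
            est = average_interaction(refit, null_model, contrast, sample)
            vals.append(est.estimate)
        except Exception as exc:
            failures += 1
            log.debug("bootstrap replicate %d failed: %s", rep, exc)
    if failures > 0.05 * method.replicates:
        raise RuntimeError(f"{failures}/{method.replicates} bootstrap "
                           "replicates failed to refit")
    if failures:
        log.warning("%d bootstrap replicates failed and were skipped", failures)
    vals = np.asarray(vals)
    alpha = 1.0 - method.level
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(np.std(vals, ddof=1)), (float(lo), float(hi))


def significance(estimate: InteractionEstimate) -> str:
    """Classify an estimate with attached CI against its null model.

    ``synergistic``/``antagonistic`` label positive/negative deviations by
    sign alone; whether a positive deviation is biologically a stronger net
    effect depends on the direction of the response.
    """
    if estimate.ci is None:
        raise ValueError("estimate has no confidence interval attached")
    lo, hi = estimate.ci
    if lo <= 0.0 <= hi:
        return "null-consistent"
    return "synergistic" if estimate.estimate > 0 else "antagonistic"


def estimate_with_uncertainty(model: FittedModel, null_model: str,
                              contrast: ContrastSpec,
                              data: pd.DataFrame | None = None,
                              method: UncertaintyMethod = UncertaintyMethod()
                              ) -> InteractionEstimate:
    """Average interaction with se and CI attached by the chosen method."""
    est = average_interaction(model, null_model, contrast, data)
    fn = average_interaction_function(model, null_model, contrast, data)
    if method.kind == "delta":
        se = delta_se(model, fn, method.covariance_variant, null_model)
        from scipy import stats

        z = stats.norm.ppf(1 - (1 - method.level) / 2)
        ci = (est.estimate - z * se, est.estimate + z * se)
        draws = None
    elif method.kind == "kr":
        se, ci = kr_interval(model, fn, method)
        draws = method.draws
    else:
        se, ci = bootstrap_interval(model.data if data is None else data,
                                    model.spec, null_model, contrast, method)
        draws = None
    return replace_fields(est, se=se, ci=ci, level=method.level,
                          method=method.kind, draws=draws,
                          replicates=(method.replicates
                                      if method.kind == "bootstrap" else None),
                          seed=method.seed)


def replace_fields(est: InteractionEstimate, **kw) -> InteractionEstimate:
    for k, v in kw.items():
        setattr(est, k, v)
    if est.ci is not None and est.ci[0] > est.ci[1]:
        raise ValueError("CI lower bound exceeds upper bound")
    return est


def observationwise_with_uncertainty(model: FittedModel, null_model: str,
                                     contrast: ContrastSpec,
                                     data: pd.DataFrame | None = None,
                                     method: UncertaintyMethod = UncertaintyMethod()
                                     ) -> pd.DataFrame:
    """Observation-wise estimates with *pointwise* Krinsky–Robb intervals.

    No multiplicity correction is applied; the ``n_intervals`` attribute
    reports how many simultaneous intervals were produced so users can
    correct (e.g. Bonferroni on the level) if they interpret pointwise
    deviations.
    """
    if method.kind != "kr":
        raise ValueError("pointwise intervals are computed with kr draws")
    fn = observationwise_function(model, null_model, contrast, data)
    rng = np.random.default_rng(method.seed)
    V = _select_cov(model, method.covariance_variant)
    draws = _mvn_draws(model.coefficients, V, method.draws, rng)
    vals = np.asarray(fn(draws), float)          # (n_obs, n_draws)
    point = np.asarray(fn(model.coefficients), float)
    alpha = 1.0 - method.level
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(vals, 100 * alpha / 2, axis=1)
        hi = np.nanpercentile(vals, 100 * (1 - alpha / 2), axis=1)
        se = np.nanstd(vals, axis=1, ddof=1)
    out = pd.DataFrame({"estimate": point, "se": se, "lower": lo, "upper": hi})
    out.attrs["n_intervals"] = len(out)
    out.attrs["interval_type"] = "pointwise"
    return out
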