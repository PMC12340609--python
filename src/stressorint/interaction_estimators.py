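"""Null-model-specific interaction estimates from adjusted predictions.

For two focal stressors with control/stressor conditions ``(c_A, s_A)`` and
``(c_B, s_B)``, and ``f`` the fitted model's response-scale prediction with
covariates held at a chosen profile, the estimators are cross-differences
over the four stressor corners, standardized by
``(s_A - c_A) * (s_B - c_B)`` (factors contribute 1):

* ``int_AD = [f(s,s) - f(c,s) - f(s,c) + f(c,c)] / denom``
* ``int_MU`` is the same contrast on ``ln f``
* ``int_DO = [min(f(s,s), f(c,c)) - min(f(c,s), f(s,c))] / denom``

For gradients the observed value serves as the control condition and a
small forward step (default 0.01% of the stressor's observed range) as the
stressor condition, approximating the cross-derivative of the fitted
surface on the relevant scale. Each null model's hypothesis of no
interaction is ``int = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .model_layer import CovariateProfile, FittedModel
from .null_models import NULL_MODELS

log = logging.getLogger(__name__)

__all__ = ["Stressor", "ContrastSpec", "InteractionEstimate", "StepError",
           "interaction_estimate", "observationwise_interaction",
           "average_interaction", "grouped_interaction",
           "average_interaction_function", "observationwise_function"]


class StepError(ValueError):
    """The gradient finite-difference step underflowed to zero."""


@dataclass(frozen=True)
class Stressor:
    """One focal stressor and its control/stressor conditions.

    For factors, ``control`` and ``stress`` are the two factor levels and
    are required. For gradients they may be left ``None``: the control
    condition is then the observed value of each row and the stressor
    condition is ``control + step_fraction * observed range``.
    """

    column: str
    kind: str = "factor"
    control: object = None
    stress: object = None

    def __post_init__(self):
        if self.kind not in ("factor", "gradient"):
            raise ValueError(f"stressor kind must be factor or gradient, "
                             f"got {self.kind!r}")
        if self.kind == "factor":
            if self.control is None or self.stress is None:
                raise ValueError(f"factor stressor {self.column!r} needs "
                                 "explicit control and stress levels")
            if self.control == self.stress:
                raise ValueError("control and stress levels must differ")


@dataclass(frozen=True)
class ContrastSpec:
    stressor_a: Stressor
    stressor_b: Stressor
    step_fraction: float = 1e-4
    profile: CovariateProfile = field(default_factory=CovariateProfile)

    def __post_init__(self):
        if self.step_fraction <= 0:
            raise ValueError("step_fraction must be positive")

    def swapped(self) -> "ContrastSpec":
        return replace(self, stressor_a=self.stressor_b,
                       stressor_b=self.stressor_a)


@dataclass
class InteractionEstimate:
    """A null-model-specific interaction estimate with optional uncertainty."""

    null_model: str
    estimate: float
    n_obs: int
    per_observation: np.ndarray | None = None
    se: float | None = None
    ci: tuple[float, float] | None = None
    level: float | None = None
    method: str | None = None
    draws: int | None = None
    replicates: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("CI lower bound exceeds upper bound")
        if self.per_observation is not None:
            if abs(self.estimate - float(np.mean(self.per_observation))) > 1e-10:
                raise ValueError("estimate must equal the mean of the "
                                 "per-observation vector")


# -- corner construction ----------------------------------------------------


def _base_rows(model: FittedModel, contrast: ContrastSpec,
               data: pd.DataFrame | None) -> pd.DataFrame:
    prof = contrast.profile
    if prof.mode == "observed":
        return pd.DataFrame(data if data is not None else model.data)
    cols = (contrast.stressor_a.column, contrast.stressor_b.column)
    row = model.profile_row(prof, exclude=cols)
    for s in (contrast.stressor_a, contrast.stressor_b):
        if s.kind == "gradient" and s.control is None:
            row[s.column] = float(model.data[s.column].mean())
        else:
            row[s.column] = s.control
    return pd.DataFrame([row])


def _conditions(model: FittedModel, s: Stressor, rows: pd.DataFrame,
                step_fraction: float):
    """(control values, stressor values, denominator factor) for one stressor."""
    n = len(rows)
    if s.kind == "factor":
        return (np.full(n, s.control, dtype=object),
                np.full(n, s.stress, dtype=object), np.ones(n))
    x = model.data[s.column].to_numpy(float)
    rng = float(x.max() - x.min())
    c = (rows[s.column].to_numpy(float) if s.control is None
         else np.full(n, float(s.control)))
    if s.stress is not None:
        sv = np.full(n, float(s.stress))
    else:
        if rng <= 0:
            raise StepError(f"gradient {s.column!r} has zero observed range")
        sv = c + step_fraction * rng
    if np.any(sv == c):
        raise StepError(f"finite-difference step for {s.column!r} underflowed; "
                        "increase step_fraction")
    return c, sv, sv - c


def corner_designs(model: FittedModel, contrast: ContrastSpec,
                   data: pd.DataFrame | None = None):
    """Design matrices at the four stressor corners plus the denominator.

    Returns ``(X_cc, X_sc, X_cs, X_ss, denom)`` with one row per base
    observation; corner order is (c_A,c_B), (s_A,c_B), (c_A,s_B), (s_A,s_B).
    """
    a, b = contrast.stressor_a, contrast.stressor_b
    modelled = {c for t in model.spec.terms for c in t.columns}
    missing = {a.column, b.column} - modelled
    if missing:
        raise ValueError(f"focal stressor column(s) {sorted(missing)!r} are "
                         "not part of the fitted model's terms")
    rows = _base_rows(model, contrast, data).reset_index(drop=True)
    ca, sa, da = _conditions(model, a, rows, contrast.step_fraction)
    cb, sb, db = _conditions(model, b, rows, contrast.step_fraction)
    mats = []
    for av, bv in ((ca, cb), (sa, cb), (ca, sb), (sa, sb)):
        r = rows.copy()
        r[a.column] = av
        r[b.column] = bv
        mats.append(model.design_matrix(r))
    return (*mats, da * db)


def _corner_means(model, Xs, beta):
    from .families import resolve_link

    link = resolve_link(model.family, model.spec.link)
    return [link.inverse(X @ beta) for X in Xs]


def _rowwise_estimates(null_model: str, mus, denom):
    m_cc, m_sc, m_cs, m_ss = mus
    denom = denom if np.ndim(mus[0]) == 1 else np.asarray(denom)[:, None]
    if null_model == "AD":
        return (m_ss - m_cs - m_sc + m_cc) / denom
    if null_model == "MU":
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = [np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), np.nan)
                    for m in (m_cc, m_sc, m_cs, m_ss)]
        return (vals[3] - vals[2] - vals[1] + vals[0]) / denom
    if null_model == "DO":
        return (np.minimum(m_ss, m_cc) - np.minimum(m_cs, m_sc)) / denom
    raise ValueError(f"unknown null model {null_model!r}")


# -- public estimators ------------------------------------------------------


def interaction_estimate(model: FittedModel, null_model: str,
                         contrast: ContrastSpec, row) -> float:
    """Interaction estimate at a single covariate row."""
    rows = pd.DataFrame([row]) if isinstance(row, (dict, pd.Series)) else pd.DataFrame(row)
    vec = observationwise_interaction(model, null_model, contrast, rows)
    return float(vec[0])


def observationwise_interaction(model: FittedModel, null_model: str,
                                contrast: ContrastSpec,
                                data: pd.DataFrame | None = None) -> np.ndarray:
    """One interaction estimate per observation (covariates at observed values)."""
    if null_model not in NULL_MODELS:
        raise ValueError(f"unknown null model {null_model!r}")
    *Xs, denom = corner_designs(model, contrast, data)
    mus = _corner_means(model, Xs, model.coefficients)
    if null_model == "MU":
        bad = [i for i, m in enumerate(np.minimum.reduce(mus)) if m <= 0]
        if bad:
            raise ValueError("MU interaction undefined: non-positive corner "
                             f"prediction at row index {bad[0]}")
    return _rowwise_estimates(null_model, mus, denom)


def average_interaction(model: FittedModel, null_model: str,
                        contrast: ContrastSpec,
                        data: pd.DataFrame | None = None) -> InteractionEstimate:
    """Mean of the observation-wise estimates: the 'average interaction'."""
    base = data if data is not None else model.data
    if len(base) == 0:
        raise ValueError("no observations to average over")
    per_obs = observationwise_interaction(model, null_model, contrast, base)
    return InteractionEstimate(null_model=null_model,
                               estimate=float(np.mean(per_obs)),
                               n_obs=len(per_obs), per_observation=per_obs)


def grouped_interaction(model: FittedModel, null_model: str,
                        contrast: ContrastSpec, data: pd.DataFrame,
                        group_by: str) -> dict:
    """Average interaction separately per level of a grouping column."""
    if group_by not in data.columns:
        raise ValueError(f"group column {group_by!r} missing")
    out = {}
    for level in sorted(pd.unique(data[group_by]).tolist()):
        sub = data[data[group_by] == level]
        if len(sub) == 0:  # pragma: no cover - pandas unique precludes this
            log.warning("group %r=%r has no rows; skipped", group_by, level)
            continue
        out[level] = average_interaction(model, null_model, contrast, sub)
    return out


# -- estimators as functions of the coefficient vector ----------------------


def average_interaction_function(model: FittedModel, null_model: str,
                                 contrast: ContrastSpec,
                                 data: pd.DataFrame | None = None
                                 ) -> Callable[[np.ndarray], np.ndarray]:
    """The average interaction as a function of the coefficient vector.

    The returned callable accepts a coefficient vector ``(p,)`` or a matrix
    of draws ``(p, d)`` and returns a scalar or a length-``d`` vector;
    invalid draws (e.g. non-positive MU corners) yield NaN. This is the
    object the delta method and posterior simulation differentiate/sample.
    """
    *Xs, denom = corner_designs(model, contrast, data)

    def fn(beta: np.ndarray):
        mus = _corner_means(model, Xs, np.asarray(beta))
        est = _rowwise_estimates(null_model, mus, denom)
        return np.mean(est, axis=0)

    return fn


def observationwise_function(model: FittedModel, null_model: str,
                             contrast: ContrastSpec,
                             data: pd.DataFrame | None = None
                             ) -> Callable[[np.ndarray], np.ndarray]:
    """Row-wise counterpart of :func:`average_interaction_function`."""
    *Xs, denom = corner_designs(model, contrast, data)

    def fn(beta: np.ndarray):
        mus = _corner_means(model, Xs, np.asarray(beta))
        return _rowwise_estimates(null_model, mus, denom)

    return fn
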