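"""Type-I-error validation by simulation under a true null model.

The protocol: fit the analyst's model to the observed data; extract the
control mean and the two single-stressor mean surfaces from the fit;
combine them with the chosen null model into a joint mean surface under
which that null model holds exactly; simulate response data from the
family's distribution at those means; refit the same model structure to
each simulated dataset; and count how often the average interaction
estimate of the (true) null model is declared significant. The resulting
rejection rate should sit near the nominal level.

Simple addition can push null means outside the response's natural limits
(e.g. below zero for counts); such means are truncated to the boundary for
simulation and the truncation count is reported rather than hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import support_bounds
from .interaction_estimators import ContrastSpec, Stressor
from .model_layer import FittedModel, ModelSpec, fit_model
from .null_models import combine_null
from .uncertainty import UncertaintyMethod, estimate_with_uncertainty

log = logging.getLogger(__name__)

__all__ = ["NullSurfaces", "Type1Result", "extract_surfaces",
           "null_mean_surface", "simulate_null_dataset", "type1_error_study"]


@dataclass
class Type1Result:
    null_model: str
    reps: int
    rejections: int
    rate: float
    mc_se: float
    level: float
    seed: int
    failures: int = 0
    truncated: int = 0
    #: per-replicate rows (replicate, estimate, lower, upper, rejected)
    detail: list = None

    def to_dict(self) -> dict:
        return {"null_model": self.null_model, "reps": self.reps,
                "rejections": self.rejections, "rate": self.rate,
                "mc_se": self.mc_se, "level": self.level, "seed": self.seed,
                "failures": self.failures, "truncated": self.truncated}


class NullSurfaces:
    """Control mean plus single-stressor mean surfaces from a fitted model.

    ``f_A(a)`` is the fitted mean at stressor A value ``a`` with stressor B
    at its control condition (and vice versa); ``C`` is the mean with both
    at control. With the default observed covariate profile each quantity
    is a vector over the design rows. Gradient stressors without an
    explicit control condition use the observed minimum as control.
    """

    def __init__(self, model: FittedModel, contrast: ContrastSpec):
        self.model = model
        self.contrast = contrast
        self.family = model.family
        self.dispersion = model.dispersion

    def _control(self, s: Stressor):
        if s.kind == "factor" or s.control is not None:
            return s.control
        return float(self.model.data[s.column].min())

    def _rows(self, rows: pd.DataFrame | None) -> pd.DataFrame:
        if rows is not None:
            return pd.DataFrame(rows).reset_index(drop=True)
        return self.model.data.copy()

    def _predict(self, rows: pd.DataFrame, a=None, b=None) -> np.ndarray:
        r = rows.copy()
        sa, sb = self.contrast.stressor_a, self.contrast.stressor_b
        r[sa.column] = self._control(sa) if a is None else a
        r[sb.column] = self._control(sb) if b is None else b
        return self.model.predict_mean(r)

    def control_mean(self, rows: pd.DataFrame | None = None) -> np.ndarray:
        return self._predict(self._rows(rows))

    def f_A(self, a, rows: pd.DataFrame | None = None) -> np.ndarray:
        """Single-stressor-A mean at value(s) ``a``, B at control."""
        r = self._rows(rows)
        return self._predict(r, a=np.broadcast_to(np.asarray(a, object), (len(r),))
                             if np.ndim(a) == 0 else a)

    def f_B(self, b, rows: pd.DataFrame | None = None) -> np.ndarray:
        r = self._rows(rows)
        return self._predict(r, b=np.broadcast_to(np.asarray(b, object), (len(r),))
                             if np.ndim(b) == 0 else b)

    def components(self, rows: pd.DataFrame | None = None):
        """(C, S_A, S_B) vectors at each row's own stressor values."""
        r = self._rows(rows)
        sa, sb = self.contrast.stressor_a, self.contrast.stressor_b
        C = self._predict(r)
        SA = self._predict(r, a=r[sa.column])
        SB = self._predict(r, b=r[sb.column])
        return C, SA, SB


def extract_surfaces(model: FittedModel, contrast: ContrastSpec) -> NullSurfaces:
    return NullSurfaces(model, contrast)


def null_mean_surface(null_model: str, surfaces: NullSurfaces,
                      grid: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Null-model mean per grid row, truncated to the family's support.

    ``grid`` must contain both stressor columns and any covariates the
    model uses. Returns ``(means, n_truncated)``.
    """
    C, SA, SB = surfaces.components(grid)
    lo, hi = support_bounds(surfaces.family)
    means = np.empty(len(C))
    truncated = 0
    for i in range(len(C)):
        pred = combine_null(null_model, C[i], SA[i], SB[i], support=(lo, hi))
        if pred.out_of_support:
            truncated += 1
            means[i] = min(max(pred.value, lo), hi)
        else:
            means[i] = pred.value
    if truncated:
        log.info("%d/%d null means truncated to the support boundary",
                 truncated, len(C))
    return means, truncated


def simulate_null_dataset(null_model: str, surfaces: NullSurfaces,
                          design_rows: pd.DataFrame, seed) -> pd.DataFrame:
    """Draw one response per design row from the family at the null means."""
    rng = np.random.default_rng(seed)
    design_rows = pd.DataFrame(design_rows).reset_index(drop=True)
    means, _ = null_mean_surface(null_model, surfaces, design_rows)
    family = surfaces.family
    spec = surfaces.model.spec
    if np.any(means < 0) and family in ("poisson", "negative_binomial",
                                        "binomial"):
        raise ValueError("negative null mean after truncation")
    if family == "gaussian":
        y = rng.normal(means, np.sqrt(surfaces.dispersion))
    elif family == "poisson":
        y = rng.poisson(means).astype(float)
    elif family == "negative_binomial":
        theta = surfaces.dispersion
        y = rng.negative_binomial(theta, theta / (theta + np.maximum(means, 1e-12)))
        y = np.where(means <= 0, 0, y).astype(float)
    elif family == "binomial":
        trials = (design_rows[spec.trials].to_numpy(int)
                  if spec.trials is not None else np.ones(len(means), int))
        succ = rng.binomial(trials, np.clip(means, 0.0, 1.0))
        orig = surfaces.model.data[spec.response].to_numpy(float)
        proportions = not np.allclose(orig, np.round(orig)) or np.all(orig <= 1)
        if spec.trials is not None and not proportions:
            y = succ.astype(float)
        elif spec.trials is not None:
            y = succ / trials
        else:
            y = succ.astype(float)
    else:
        raise ValueError(f"simulation not supported for family {family!r}")
    out = design_rows.copy()
    out[spec.response] = y
    return out


def type1_error_study(data: pd.DataFrame, spec: ModelSpec,
                      contrast: ContrastSpec, null_model: str,
                      reps: int = 10_000, level: float = 0.95, seed: int = 0,
                      kr_draws: int = 10_000,
                      covariance_variant: str | None = None) -> Type1Result:
    """Rejection rate of a true null model over simulated refits.

    Each replicate owns an RNG stream derived from ``(seed, replicate)`` so
    skipped failures do not shift later replicates. Replicates whose refit
    or interval fails are excluded and counted; more than 2% failing aborts.
    """
    if reps < 100:
        raise ValueError("type-I error study needs at least 100 replicates")
    base_fit = fit_model(data, spec)
    surfaces = extract_surfaces(base_fit, contrast)
    _, truncated = null_mean_surface(null_model, surfaces, data)
    rejections = completed = failures = 0
    detail: list = []
    for rep in range(reps):
        sim = simulate_null_dataset(null_model, surfaces, data, seed=[seed, rep])
        kr_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0]
                      % (2 ** 31))
        try:
            refit = fit_model(sim, spec)
            est = estimate_with_uncertainty(
                refit, null_model, contrast, sim,
                UncertaintyMethod(kind="kr", draws=kr_draws, level=level,
                                  seed=kr_seed,
                                  covariance_variant=covariance_variant))
        except Exception as exc:
            failures += 1
            log.debug("replicate %d failed: %s", rep, exc)
            if failures > max(0.02 * reps, 2):
                raise RuntimeError(
                    f"{failures} replicates failed by replicate {rep}; "
                    f"last error: {exc}") from exc
            continue
        completed += 1
        lo, hi = est.ci
        rejected = not (lo <= 0.0 <= hi)
        if rejected:
            rejections += 1
        detail.append({"replicate": rep, "estimate": est.estimate,
                       "lower": lo, "upper": hi, "rejected": rejected})
    rate = rejections / completed
    return Type1Result(null_model=null_model, reps=completed,
                       rejections=rejections, rate=rate,
                       mc_se=float(np.sqrt(rate * (1 - rate) / completed)),
                       level=level, seed=seed, failures=failures,
                       truncated=truncated, detail=detail)
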