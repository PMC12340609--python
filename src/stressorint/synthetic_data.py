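"""Synthetic datasets with the structure of the three design archetypes.

Three experimental designs recur in multiple-stressor work and drive this
package's tests:

* a 2x2x2 full-factorial mesocosm design with overdispersed
  (negative-binomial) invertebrate counts, 64 units;
* a factor-by-gradient design: a two-level nutrient factor crossed with a
  chloride gradient, Poisson richness counts, 30 units per level;
* a two-toxicant ray design: fixed dose ratios scaled across total-toxicity
  levels, binomial survival of 10 individuals per unit (620 individuals).

A fourth generator realises the co-tolerance thought experiment: individuals
carry binary sensitivities to two stressors with a chosen dependence, and
the joint-exposure survivors are those sensitive to neither. Its limiting
regimes reproduce the null models exactly: maximal negative dependence
gives simple addition, independence the multiplicative model, and maximal
positive dependence dominance — provided survival (not mortality) is the
response.

Every generator is a pure function of its parameters and seed and returns
the table together with the generating truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GeneratedData", "CoToleranceScenario", "gen_factorial_counts",
           "gen_factor_gradient_counts", "gen_ray_design_binomial",
           "gen_cotolerance", "default_ray_surface"]


@dataclass
class GeneratedData:
    data: pd.DataFrame
    truth: dict

    def write(self, path_prefix: str | Path) -> tuple[Path, Path]:
        """CSV plus a JSON sidecar of generating truth."""
        prefix = Path(path_prefix)
        csv = prefix.with_suffix(".csv")
        meta = prefix.with_suffix(".truth.json")
        self.data.to_csv(csv, index=False)
        meta.write_text(json.dumps(_jsonable(self.truth), indent=2))
        return csv, meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if callable(obj):
        return repr(obj)
    return obj


# -- 2x2x2 factorial negative-binomial counts -------------------------------


def gen_factorial_counts(n_per_cell: int = 8, mu_control: float = 100.0,
                         effects: dict | None = None,
                         interactions: dict | None = None,
                         dispersion: float = 12.0, seed: int = 0,
                         factors: tuple[str, str, str] = ("sal", "sed", "flow"),
                         response: str = "abundance") -> GeneratedData:
    """Full-factorial counts for three binary stressors (64 rows by default).

    ``effects`` maps factor name to its single-stressor effect on the log
    scale; ``interactions`` maps tuples of factor names to log-scale
    interaction coefficients (default: none, so the multiplicative null
    model holds in the generating truth). ``dispersion`` is the
    negative-binomial size theta (variance ``mu + mu^2/theta``).
    """
    if effects is None:
        effects = {factors[0]: -0.7, factors[1]: -0.9, factors[2]: -0.5}
    interactions = dict(interactions or {})
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    cells = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    rows = []
    for cell in cells:
        x = dict(zip(factors, cell))
        log_mu = np.log(mu_control) + sum(effects.get(f, 0.0) * x[f]
                                          for f in factors)
        for key, coef in interactions.items():
            log_mu += coef * np.prod([x[f] for f in key])
        mu = np.exp(log_mu)
        if not np.isfinite(mu):
            raise ValueError(f"non-finite cell mean for {x}")
        y = rng.negative_binomial(dispersion, dispersion / (dispersion + mu),
                                  size=n_per_cell)
        for v in y:
            rows.append({**x, response: float(v)})
    data = pd.DataFrame(rows)
    truth = {"design": "factorial_2x2x2", "n_per_cell": n_per_cell,
             "mu_control": mu_control, "effects": effects,
             "interactions": {",".join(k): v for k, v in interactions.items()},
             "dispersion": dispersion, "family": "negative_binomial",
             "seed": seed}
    return GeneratedData(data, truth)


# -- factor x gradient Poisson counts ---------------------------------------


def _default_richness_curve(x: np.ndarray) -> np.ndarray:
    # log mean falling with the gradient, mildly curved
    return np.log(25.0) - 1.2 * (x / x.max() if x.max() > 0 else x) ** 2


def gen_factor_gradient_counts(n_per_level: int = 30,
                               gradient_range: tuple[float, float] = (0.41, 1500.0),
                               curves: dict | None = None,
                               levels: tuple[str, str] = ("ambient", "high"),
                               gradient: str = "chloride", factor_col: str = "nut",
                               response: str = "richness",
                               seed: int = 0) -> GeneratedData:
    """Poisson counts along a gradient within each level of a binary factor.

    ``curves`` maps factor level to a callable giving the log mean as a
    function of the gradient value; by default both levels share one
    decreasing curve, so no factor effect and no interaction exist in the
    generating truth.
    """
    lo, hi = gradient_range
    if not hi > lo:
        raise ValueError("gradient range must be strictly increasing")
    rng = np.random.default_rng(seed)
    xgrid = np.geomspace(max(lo, 1e-6), hi, n_per_level)
    rows = []
    for level in levels:
        fun = (curves or {}).get(level, _default_richness_curve)
        log_mu = np.asarray(fun(xgrid), float)
        mu = np.exp(log_mu)
        if np.any(~np.isfinite(mu)) or np.any(mu < 0):
            raise ValueError(f"invalid mean curve for level {level!r}")
        y = rng.poisson(mu)
        for xv, yv in zip(xgrid, y):
            rows.append({gradient: xv, factor_col: level, response: float(yv)})
    data = pd.DataFrame(rows)
    truth = {"design": "factor_gradient", "n_per_level": n_per_level,
             "gradient_range": list(gradient_range), "levels": list(levels),
             "curves": {lv: repr((curves or {}).get(lv, _default_richness_curve))
                        for lv in levels},
             "family": "poisson", "seed": seed}
    return GeneratedData(data, truth)


# -- two-toxicant ray design with binomial survival -------------------------


def default_ray_surface(control_survival: float = 0.95,
                        slope_a: float = 1.6, slope_b: float = 1.6):
    """Multiplicative-null-true joint survival surface in toxic units.

    Each toxicant reduces survival by the relative factor ``1/(1 + d^k)``
    (survival 50% at one toxic unit); relative effects multiply, so the
    multiplicative null model holds exactly in the generating truth.
    """

    def surface(dose_a, dose_b):
        qa = 1.0 / (1.0 + np.asarray(dose_a, float) ** slope_a)
        qb = 1.0 / (1.0 + np.asarray(dose_b, float) ** slope_b)
        return control_survival * qa * qb

    return surface


def gen_ray_design_binomial(ratios=((1.0, 0.0), (0.67, 0.33), (0.5, 0.5),
                                    (0.33, 0.67), (0.0, 1.0)),
                            toxicity_levels=(0.125, 0.25, 0.5, 1.0, 2.0, 4.0),
                            replicates: int = 2, trials: int = 10,
                            control_replicates: int = 2,
                            surface=None, seed: int = 0,
                            dose_a: str = "dose_a", dose_b: str = "dose_b",
                            response: str = "survived") -> GeneratedData:
    """Ray (mixture) design: fixed dose ratios scaled over total toxicity.

    Doses are in toxic units; each unit holds ``trials`` individuals and
    the response is the binomial number of survivors. The default template
    (5 ratios x 6 levels x 2 replicates + 2 controls, 10 individuals each)
    totals 620 individuals.
    """
    for r in ratios:
        if abs(sum(r) - 1.0) > 1e-9:
            raise ValueError(f"dose ratio {r} does not sum to 1")
    if surface is None:
        surface = default_ray_surface()
    rng = np.random.default_rng(seed)
    rows = []
    combos = [(0.0, 0.0)] * control_replicates + [
        (ra * tu, rb * tu)
        for ra, rb in ratios for tu in toxicity_levels for _ in range(replicates)]
    for da, db in combos:
        p = float(surface(da, db))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"survival probability {p} outside [0, 1] at "
                             f"doses ({da}, {db})")
        rows.append({dose_a: da, dose_b: db, "trials": trials,
                     response: float(rng.binomial(trials, p))})
    data = pd.DataFrame(rows)
    truth = {"design": "ray_mixture", "ratios": [list(r) for r in ratios],
             "toxicity_levels": list(toxicity_levels),
             "replicates": replicates, "trials": trials,
             "control_replicates": control_replicates,
             "total_individuals": len(data) * trials,
             "surface": repr(surface), "family": "binomial", "seed": seed}
    return GeneratedData(data, truth)


# -- co-tolerance scenarios -------------------------------------------------


@dataclass(frozen=True)
class CoToleranceScenario:
    """Binary-sensitivity population with a chosen sensitivity dependence.

    ``rho`` is the latent Gaussian-copula correlation of the two
    sensitivities; the end points map to the Frechet-Hoeffding bound
    couplings (comonotone at +1, countermonotone at -1).
    ``baseline_mortality`` kills individuals independently of either
    sensitivity in every treatment, including the control.
    """

    n: int = 1000
    rho: float = 0.0
    p_a: float = 0.3
    p_b: float = 0.3
    baseline_mortality: float = 0.0

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(
                "latent correlation outside the Frechet-Hoeffding feasible "
                f"range [-1, 1]: {self.rho}")
        for p in (self.p_a, self.p_b, self.baseline_mortality):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n < 1:
            raise ValueError("need at least one individual")


@dataclass
class CoToleranceCounts:
    n: int
    survivors: dict = field(default_factory=dict)   # per treatment C/A/B/AB
    deaths: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def survival_proportions(self) -> dict:
        return {k: v / self.n for k, v in self.survivors.items()}

    def mortality_proportions(self) -> dict:
        return {k: v / self.n for k, v in self.deaths.items()}


def gen_cotolerance(scenario: CoToleranceScenario, seed: int = 0
                    ) -> CoToleranceCounts:
    """Survivor counts for control, single and joint exposures.

    Each individual carries binary sensitivities to the two stressors with
    marginal kill probabilities ``p_a``/``p_b`` and the scenario's
    dependence; joint-exposure survivors are those sensitive to neither.
    """
    rng = np.random.default_rng(seed)
    n = scenario.n
    if scenario.rho == 1.0:
        u = rng.uniform(size=n)
        ua, ub = u, u
    elif scenario.rho == -1.0:
        u = rng.uniform(size=n)
        ua, ub = u, 1.0 - u
    else:
        cov = [[1.0, scenario.rho], [scenario.rho, 1.0]]
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n,
                                    method="cholesky")
        ua, ub = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
    sens_a = ua < scenario.p_a
    sens_b = ub < scenario.p_b
    alive_base = rng.uniform(size=n) >= scenario.baseline_mortality
    survivors = {
        "C": int(alive_base.sum()),
        "A": int((alive_base & ~sens_a).sum()),
        "B": int((alive_base & ~sens_b).sum()),
        "AB": int((alive_base & ~sens_a & ~sens_b).sum()),
    }
    deaths = {k: n - v for k, v in survivors.items()}
    truth = {"n": n, "rho": scenario.rho, "p_a": scenario.p_a,
             "p_b": scenario.p_b,
             "baseline_mortality": scenario.baseline_mortality, "seed": seed,
             "expected_ab_survival": _expected_ab_survival(scenario)}
    return CoToleranceCounts(n=n, survivors=survivors, deaths=deaths,
                             truth=truth)


def _expected_ab_survival(sc: CoToleranceScenario) -> float:
    """E[joint-exposure survival proportion] under the scenario."""
    if sc.rho == 1.0:
        p_both = min(sc.p_a, sc.p_b)
    elif sc.rho == -1.0:
        p_both = max(0.0, sc.p_a + sc.p_b - 1.0)
    elif sc.rho == 0.0:
        p_both = sc.p_a * sc.p_b
    else:
        lim = stats.norm.ppf([sc.p_a, sc.p_b])
        p_both = float(stats.multivariate_normal(
            [0.0, 0.0], [[1.0, sc.rho], [sc.rho, 1.0]]).cdf(lim))
    neither = 1.0 - sc.p_a - sc.p_b + p_both
    return (1.0 - sc.baseline_mortality) * neither
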