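"""Advisory model diagnostics based on randomized quantile residuals.

For a well-specified model the randomized quantile residuals are standard
normal; the checks below (dispersion of the residuals, uniformity of their
probability transforms) are reported for the analyst to judge and never
gate an analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .model_layer import FittedModel


def randomized_quantile_residuals(model: FittedModel, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    y = model.data[model.spec.response].to_numpy(float)
    mu = model.fitted_means
    fam = model.family
    if fam == "gaussian":
        u = stats.norm.cdf(y, mu, np.sqrt(model.dispersion))
    elif fam == "poisson":
        lo = stats.poisson.cdf(y - 1, mu)
        hi = stats.poisson.cdf(y, mu)
        u = rng.uniform(lo, hi)
    elif fam == "negative_binomial":
        theta = model.dispersion
        p = theta / (theta + mu)
        lo = stats.nbinom.cdf(y - 1, theta, p)
        hi = stats.nbinom.cdf(y, theta, p)
        u = rng.uniform(lo, hi)
    elif fam == "binomial":
        if model.spec.trials is not None:
            trials = model.data[model.spec.trials].to_numpy(float)
        else:
            trials = np.ones_like(y)
        succ = y if np.any(y > 1) else np.round(y * trials)
        lo = stats.binom.cdf(succ - 1, trials.astype(int), mu)
        hi = stats.binom.cdf(succ, trials.astype(int), mu)
        u = rng.uniform(lo, hi)
    else:
        raise ValueError(f"no quantile residuals for family {fam!r}")
    u = np.clip(u, 1e-10, 1 - 1e-10)
    return stats.norm.ppf(u)


def diagnostic_summary(model: FittedModel, seed: int = 0) -> dict:
    """Dispersion and uniformity checks; advisory only."""
    r = randomized_quantile_residuals(model, seed)
    ks = stats.kstest(r, "norm")
    return {
        "n": int(len(r)),
        "rqr_variance": float(np.var(r, ddof=1)),
        "rqr_mean": float(np.mean(r)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "note": "randomized quantile residuals should be approximately "
                "standard normal for a well-specified model",
    }
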