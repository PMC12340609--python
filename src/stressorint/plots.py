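"""Conditional plots: one stressor on x, faceted by the other.

Under the simple addition null model the conditional curves are parallel on
the response scale; under the multiplicative null model they are parallel
on the log scale; under dominance the curves of the weaker stressor
overlay (identical, not merely parallel) wherever it is dominated. Plots
are drawn symmetrically: each focal stressor takes a turn on the x axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .interaction_estimators import ContrastSpec, Stressor
from .model_layer import CovariateProfile, FittedModel

__all__ = ["conditional_curves", "conditional_plot"]

_N_GRID = 60
_GRADIENT_FACETS = (0.05, 0.5, 0.95)  # quantiles of the conditioning gradient


def _axis_values(model: FittedModel, s: Stressor):
    if s.kind == "factor":
        return [s.control, s.stress]
    x = model.data[s.column].to_numpy(float)
    return np.linspace(x.min(), x.max(), _N_GRID)


def _facet_values(model: FittedModel, s: Stressor):
    if s.kind == "factor":
        return [s.control, s.stress]
    x = model.data[s.column].to_numpy(float)
    return [float(np.quantile(x, q)) for q in _GRADIENT_FACETS]


def conditional_curves(model: FittedModel, contrast: ContrastSpec
                       ) -> pd.DataFrame:
    """Adjusted predictions for both symmetric conditional views.

    Covariates are held at the training means/modes. Columns: ``focal``
    (the stressor on x), ``x``, ``facet`` (the conditioning stressor's
    value) and ``mean``.
    """
    base = model.profile_row(CovariateProfile("mean"),
                             exclude=(contrast.stressor_a.column,
                                      contrast.stressor_b.column))
    frames = []
    pairs = [(contrast.stressor_a, contrast.stressor_b),
             (contrast.stressor_b, contrast.stressor_a)]
    for focal, other in pairs:
        xs = _axis_values(model, focal)
        for facet in _facet_values(model, other):
            rows = pd.DataFrame([{**base, focal.column: xv, other.column: facet}
                                 for xv in xs])
            mu = model.predict_mean(rows)
            frames.append(pd.DataFrame({"focal": focal.column, "x": xs,
                                        "facet": facet, "mean": mu}))
    return pd.concat(frames, ignore_index=True)


def conditional_plot(model: FittedModel, contrast: ContrastSpec,
                     scale: str = "response", path=None):
    """Two-panel symmetric conditional plot; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if scale not in ("response", "log"):
        raise ValueError("scale must be 'response' or 'log'")
    curves = conditional_curves(model, contrast)
    if scale == "log" and (curves["mean"] <= 0).any():
        raise ValueError("log scale requested but predictions include "
                         "non-positive values")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, (focal, sub) in zip(axes, curves.groupby("focal", sort=False)):
        for facet, line in sub.groupby("facet", sort=False):
            numeric = np.issubdtype(np.asarray(line["x"]).dtype, np.number)
            if numeric:
                ax.plot(line["x"], line["mean"], label=f"{facet}")
            else:
                ax.plot(range(len(line)), line["mean"], "o-", label=f"{facet}")
                ax.set_xticks(range(len(line)), line["x"])
        if scale == "log":
            ax.set_yscale("log")
        ax.set_xlabel(focal)
        ax.legend(title="given", fontsize=8)
    axes[0].set_ylabel(model.spec.response
                       + (" (log scale)" if scale == "log" else ""))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
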