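"""Multiple-stressor null models (AD, MU, DO) and effect measures.

A null model predicts the joint two-stressor response ``S_AB`` from the
control response ``C`` and the single-stressor responses ``S_A`` and
``S_B``, all on the response scale:

* **AD** (simple addition): ``S_AB = S_A + S_B - C`` — absolute effects add.
* **MU** (multiplicative):  ``S_AB = S_A * S_B / C`` — relative effects
  multiply (independent "double hits" under uncorrelated sensitivities).
* **DO** (dominance): ``min(C, S_AB) = min(S_A, S_B)`` — the worse single
  stressor takes precedence (positively correlated sensitivities). This
  pins the joint prediction down only when at least one stressor is
  harmful; the both-beneficial case is flagged, not guessed.

AD can cross the natural limits of a response (e.g. negative counts); such
predictions are returned with a flag rather than clipped, because the
crossing is an interpretive issue, not a numerical one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NULL_MODELS = ("AD", "MU", "DO")

__all__ = ["NULL_MODELS", "NullPrediction", "combine_null", "effect_measure"]


@dataclass(frozen=True)
class NullPrediction:
    value: float
    #: prediction lies outside the family's natural support bounds
    out_of_support: bool = False
    #: DO only: both stressors beneficial, outside the regime the dominance
    #: rule pins down; the control response is returned
    out_of_regime: bool = False


def combine_null(null_model: str, C: float, S_A: float, S_B: float,
                 support: tuple[float, float] = (-np.inf, np.inf)
                 ) -> NullPrediction:
    """Joint-response prediction of one null model for a response triple.

    ``support`` gives the natural limits of the response (e.g. ``(0, inf)``
    for counts, ``(0, 1)`` for proportions); predictions beyond them are
    flagged, never clipped.
    """
    if null_model not in NULL_MODELS:
        raise ValueError(f"unknown null model {null_model!r}")
    C, S_A, S_B = float(C), float(S_A), float(S_B)
    out_of_regime = False
    if null_model == "AD":
        value = S_A + S_B - C
    elif null_model == "MU":
        if C <= 0:
            raise ValueError("MU requires a positive control response C")
        value = S_A * S_B / C
    else:  # DO
        worst = min(S_A, S_B)
        if worst <= C:
            value = worst
        else:
            # both responses above control: dominance only constrains
            # min(C, S_AB) = min(S_A, S_B) > C, which is unsatisfiable;
            # return C and flag the prediction as outside the DO regime
            value = C
            out_of_regime = True
    lo, hi = support
    return NullPrediction(value, out_of_support=not (lo <= value <= hi),
                          out_of_regime=out_of_regime)


def effect_measure(kind: str, C: float, S: float) -> float:
    """Single-stressor effect size implied by a link function.

    ``DIFF = S - C`` (identity), ``LRR = ln(S/C)`` (log),
    ``LOR = logit(S) - logit(C)`` (logit).
    """
    C, S = float(C), float(S)
    if kind == "DIFF":
        return S - C
    if kind == "LRR":
        if C <= 0 or S <= 0:
            raise ValueError("LRR requires strictly positive responses")
        return float(np.log(S / C))
    if kind == "LOR":
        if not (0 < C < 1 and 0 < S < 1):
            raise ValueError("LOR requires responses strictly inside (0, 1)")
        return float(np.log(S / (1 - S)) - np.log(C / (1 - C)))
    raise ValueError(f"unknown effect measure {kind!r}")
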