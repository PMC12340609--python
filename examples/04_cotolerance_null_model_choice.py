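"""Co-tolerance thought experiment: which null model fits which biology?

Individuals carry binary sensitivities to two stressors. The correlation of
those sensitivities decides the right null model for the joint survival:
disjoint sensitivity sets (rho = -1) give simple addition, independent
sensitivities (rho = 0) the multiplicative model, nested sensitivities
(rho = +1) dominance. This only works with survival as the response —
recoding to mortality breaks the multiplicative prediction.
"""

import stressorint as si
from stressorint.synthetic_data import CoToleranceScenario, gen_cotolerance

p_a, p_b, n = 0.3, 0.25, 200_000
for rho, null_model in ((-1.0, "AD"), (0.0, "MU"), (1.0, "DO")):
    sc = CoToleranceScenario(n=n, rho=rho, p_a=p_a, p_b=p_b)
    counts = gen_cotolerance(sc, seed=4)
    s = counts.survival_proportions()
    predicted = si.combine_null(null_model, s["C"], s["A"], s["B"]).value
    print(f"rho={rho:+.0f}: observed AB survival {s['AB']:.4f}, "
          f"{null_model} prediction {predicted:.4f}")
print("  (matching values: the null model implied by the sensitivity "
      "correlation reproduces the joint response)")

sc = CoToleranceScenario(n=n, rho=0.0, p_a=p_a, p_b=p_b,
                         baseline_mortality=0.1)
counts = gen_cotolerance(sc, seed=4)
s, m = counts.survival_proportions(), counts.mortality_proportions()
print(f"mortality recoding: observed AB deaths {m['AB']:.4f} vs MU-on-deaths "
      f"prediction {si.combine_null('MU', m['C'], m['A'], m['B']).value:.4f}"
      " -> MU must be applied to survival, not mortality")
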