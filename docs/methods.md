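# Methods

## The problem

Multiple-stressor studies ask whether two co-occurring stressors interact:
whether their joint effect on a biological response (abundance, richness,
survival) is stronger or weaker than a *null model* predicts from the
control response `C` and the single-stressor responses `S_A`, `S_B`. Three
null models from the co-tolerance framework are implemented:

| model | joint prediction | mechanistic reading |
|---|---|---|
| AD (simple addition) | `S_AB = S_A + S_B − C` | absolute effects add; disjoint sensitivity sets |
| MU (multiplicative) | `S_AB = S_A · S_B / C` | relative effects multiply; independent sensitivities |
| DO (dominance) | `min(C, S_AB) = min(S_A, S_B)` | worst stressor wins; nested sensitivity sets |

The statistical difficulty is that a regression model's interaction
coefficient tests whichever null model the link function imposes (identity
→ AD, log → MU, logit → neither). The package therefore separates model
fitting from hypothesis testing: fit whatever generalized model suits the
data, then compute *null-model-specific interaction estimates* from the
fitted model's response-scale predictions.

## Interaction estimates

With `f(a, b; x)` the fitted mean at stressor values `(a, b)` and
covariates `x`, and corners `(c_A, s_A) × (c_B, s_B)`:

    int_AD = [f(s,s) − f(c,s) − f(s,c) + f(c,c)] / [(s_A−c_A)(s_B−c_B)]
    int_MU = same contrast applied to ln f
    int_DO = [min(f(s,s), f(c,c)) − min(f(c,s), f(s,c))] / [(s_A−c_A)(s_B−c_B)]

Each null hypothesis is `int = 0`. Factors contribute 1 to the
denominator. For gradients the observed value is the control condition and
a forward step of `step_fraction × observed range` (default `1e-4`, i.e.
0.01% of the range) the stressor condition, approximating the
cross-derivative of the fitted surface on the response (AD, DO) or log
(MU) scale. Forward rather than central differences keep the evaluation
inside the observed support except for a `1e-4`-range overshoot at the top
end, which the spline bases tolerate via a 2% domain pad. Covariates are
held at observed values by default (estimates are averaged over
observations: the *average interaction*), or at means/modes or
user-chosen representative values.

Degenerate inputs: MU requires strictly positive corner predictions and
raises rather than epsilon-padding (padding would bias the log contrast).
The DO `min` is evaluated literally, with ties resolved by value. When
both stressors are beneficial (`min(S_A, S_B) > C`) the dominance rule is
unsatisfiable as stated; `combine_null` returns `C` with an
`out_of_regime` flag rather than guessing. AD predictions beyond the
response's natural limits are flagged, never clipped.

## Model layer

Parametric models (gaussian, Poisson, negative binomial, binomial, beta;
identity/log/logit links) are fitted through statsmodels; the
negative-binomial size `theta` (variance `mu + mu²/theta`) is estimated by
maximum likelihood, and the beta family is restricted to the logit link
and parametric terms. Design matrices are built in-package so that
predictions under perturbed coefficient vectors — what the uncertainty
machinery needs — are exact linear-algebra operations.

Models with smooth terms use an in-package penalized-spline engine: cubic
B-spline bases (default size 10) with second-order difference penalties
(P-splines), sum-to-zero constraints for identifiability, penalized IRLS
with step halving, and smoothing parameters chosen by minimizing a
restricted-likelihood score (exact Gaussian REML; the standard
Laplace/working-model approximation for other families). Factor-smooth
interactions are difference smoothers (one penalized deviation curve per
non-reference level); gradient-gradient interactions are tensor-product
interaction smooths (row-wise Kronecker of marginally centred bases, one
smoothing parameter per margin). P-splines were chosen over thin-plate
bases because they are simple to build exactly from scipy primitives and
behave equivalently for these one- and two-dimensional smooths.

The coefficient covariance at the selected smoothness is the Bayesian
`phi (X'WX + S_λ)⁻¹`. The *unconditional* variant adds a first-order
smoothing-parameter-uncertainty correction `J V_ρ J'` (finite-difference
`J = dβ/dρ`, `V_ρ` the inverse curvature of the REML score, negative
curvature eigenvalues truncated so the correction is PSD). If the
correction is numerically unavailable the conditional covariance is
returned with a logged warning; intervals are then less conservative. For
purely parametric models the two variants coincide. Both Wald and
likelihood-ratio tests are exposed for parametric fits, since either may
be wanted for main-effect summaries.

## Uncertainty

Interaction estimates are nonlinear functions of the coefficients; three
routes to a standard error and CI are provided.

* **Delta method**: `se = sqrt(g'Vg)` with `g` a central-difference
  gradient (relative step `1e-6`). Unreliable for DO near points where the
  `min` switches branch (a logged warning says so).
* **Krinsky–Robb** (default): draw coefficient vectors from
  `N(beta_hat, V)` — `V` unconditional by default for smooth models —
  evaluate the estimator per draw, and take the sample sd and percentile
  interval. Defaults: 10,000 draws, 95% level. Percentile rather than
  normal-theory intervals honour the skewness that motivates working on
  the response scale in the first place; both the draw count and the
  construction are config-exposed since neither is canonical. Draws
  violating the estimator's domain are discarded and counted; >1%
  discarded aborts.
* **Case bootstrap**: rows resampled with replacement (optionally
  stratified by treatment cell), model refitted, estimate recomputed;
  default 2,000 replicates; >5% refit failures aborts.

Significance is two-sided: the null model is rejected when the CI excludes
zero. Observation-wise intervals are pointwise; the result carries
`n_intervals` so users can correct for multiplicity. The classification
labels positive/negative deviations by sign alone; mapping sign to
biological synergism/antagonism depends on the response's effect
direction and is left to the analyst.

## Type-I-error protocol

`type1_error_study` validates the whole pipeline for a given dataset and
model: fit the model, extract the control mean and single-stressor mean
surfaces (the other stressor held at its control condition; gradients
without an explicit control use the observed minimum; covariates at
observed values), recombine them under the chosen null model so it holds
exactly, simulate responses from the family's distribution (negative
binomial with the estimated size; binomial with each row's trial count),
refit the same model structure, and count rejections of the average
interaction over replicates (default 10,000; tests and examples use
hundreds to low thousands). AD means that cross the response's natural
limits are truncated to the boundary for simulation and the truncation
count is reported. Each replicate derives its RNG stream from
`(seed, replicate)`, so skipped failures do not shift later replicates;
more than 2% failed replicates aborts.

## Synthetic data

The generators emulate the statistical structure of three archetypal
designs — they are study conditions, not conveniences:

* **Factorial 2×2×2** (`gen_factorial_counts`): 8 units per cell (64
  rows), negative-binomial counts, control mean 100, log-scale
  single-stressor effects (−0.7, −0.9, −0.5), no generating interactions,
  size 12 — magnitudes typical of sensitive-invertebrate abundances in
  mesocosm experiments with strong stressor treatments.
* **Factor × gradient** (`gen_factor_gradient_counts`): 30 units per
  nutrient level, chloride 0.41–1500 (geometric spacing), Poisson
  richness with log mean falling from 25 by ~1.2 log units across the
  gradient, identical curves in both levels by default.
* **Ray mixture** (`gen_ray_design_binomial`): 5 dose ratios × 6 total
  toxic-unit levels × 2 replicates + 2 controls, 10 individuals per unit
  (620 total). The default surface is multiplicative-null-true
  (independent action): control survival 0.95, relative survival
  `1/(1+d^1.6)` per toxicant (50% at one toxic unit).
* **Co-tolerance** (`gen_cotolerance`): binary sensitivities with
  marginal kill probabilities coupled by a Gaussian copula;
  `rho = ±1` map to the Fréchet–Hoeffding comonotone/countermonotone
  couplings. The limits reproduce AD/MU/DO exactly (in expectation) at
  `rho = −1/0/+1`, and only for survival — mortality recoding breaks MU
  and DO, which the tests assert.

What the generators do *not* emulate: ecological covariate structure
(temperature logs, block effects), species composition, or
continuous-trait (e.g. biomass) aggregation across individuals, where the
co-tolerance correspondence itself breaks down. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
sampling models, not robustness to real-data messiness.

## Known limitations

* Smoothing bias: penalized smooths shrink weakly identified interaction
  surfaces toward zero. When the refit family cannot represent the null
  surface without the interaction smooth (e.g. a logit-link binomial GAM
  under a multiplicative-true surface with only 10 individuals per unit),
  the shrunk fit carries a systematic nonzero interaction estimate and the
  type-I error of `int_MU` can be badly inflated. The bias disappears as
  information grows (verified by the test suite at large trial counts),
  and the nominal behaviour of the protocol itself is verified with a
  log-link refit in which the surface is representable. Practical advice:
  always run `type1_error_study` for the actual design and model before
  interpreting a GAM-based interaction test, and treat smooth-model
  rejection rates as approximate — the unconditional covariance
  (over-covering) and smoothing bias (anti-conservative) pull in opposite
  directions.
* Delta-method SEs for DO are unreliable near min-switch points; use
  Krinsky–Robb.
* No random effects, no Bayesian fitting, no simultaneous confidence
  bands, no three-way interaction estimators, and no
  concentration-addition/stress-addition null models.
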