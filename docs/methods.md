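# Methods

## The transparency model

The episcotister model treats a transparent layer as a convex mixture: a
background pixel of luminance `b ∈ [0, 1]` seen through a layer with
transmittance `α ∈ [0, 1]` and reflectance-when-opaque `t ∈ [0, 1]`
becomes `p = α·b + t·(1 − α)`. The map is affine in the image, sends
[0, 1] into [0, 1] (output is clipped defensively anyway), has a fixed
point at `b = t`, and two layers in sequence compose into a single layer
with `α' = α₁α₂`. Michelson contrast can only be reduced by a layer;
equality holds exactly for `t = 0` (pure scaling) or `α = 1` (identity),
with the degenerate corner `t = 0, α = 0` collapsing the image to black
(contrast 0 by the all-black convention). Histogram skewness uses the
population estimator; zero-variance regions report skewness 0 and an
all-black region reports contrast 0, both with a logged warning, so
summaries never propagate NaN.

Two layer parameterizations are used throughout: the paired-comparison
configuration varies reflectance `t ∈ {0, 0.33, 0.66, 1}` at fixed
`α = 0.5`, and the matching configuration fixes `t = 0.5` and varies
`α ∈ {0.2, 0.4, 0.6, 0.8}`. Both are plain `FilterSpec` values, so any
other combination is equally expressible.

## Conjoint measurement

Binary "which looks glossier?" judgments over a gloss-level × layer-level
grid are modelled Thurstonially: the decision variable is the difference
of perceptual values plus a single Gaussian judgment error, giving a
probit likelihood. Three nested observer models are fitted:

| model | decision variable | free parameters (n_g × n_f grid) |
|---|---|---|
| independent | `ψᵍᵢ − ψᵍₖ` | n_g − 1 |
| additive | `(ψᵍᵢ + ψʳⱼ) − (ψᵍₖ + ψʳₗ)` | (n_g − 1) + (n_f − 1) |
| full | adds interaction `ψᵍʳ` | n_g·n_f − 1 |

**Identifiability.** σ is fixed at 1 (scales are in noise-SD, d′-like
units) and the first level of each dimension is anchored at 0; the full
model is parameterized by per-stimulus utilities with the (0, 0) stimulus
anchored, then decomposed so the interaction matrix has zero first row
and column. These conventions make the free-parameter counts above exact
and the likelihood-ratio degrees of freedom (3 and 9 on a 4 × 4 grid)
follow by subtraction.

**Estimation.** The negative log-likelihood is convex in the anchored
parameters; it is minimized with analytic gradients (L-BFGS-B, relative
tolerance ~1e-12, ≤ 500 iterations) from two starts (zeros and one fixed
random start). A tiny ridge (1e-6·‖ψ‖²) regularizes complete separation —
low-repetition designs can produce empirical choice proportions of 0 or
1, which would push parameters to infinity — and parameters are bounded
at ±10; a fit pinned at that cap is flagged `separated`, not raised. The
reported log-likelihood is unpenalized, evaluated after a final
unpenalized polish, so nested log-likelihoods are directly comparable
(LL_independent ≤ LL_additive ≤ LL_full holds to optimizer tolerance).
An independent cross-check in the test suite fits the identical
signed-indicator design matrix with a binomial/probit GLM and agrees to
1e-4 in log-likelihood.

**Model comparison and aggregation.** Nested models are compared with
`2·ΔLL ~ χ²(Δdf)`; per-observer tests in a cohort of m observers use the
Bonferroni level `α/m` (0.05/8 = 0.00625). Group scale curves divide each
observer's estimates by that observer's maximum estimate over both
dimensions before averaging (normalization first, then mean ± SEM across
observers); observers whose maximum estimate is ≤ 0 carry no usable scale
and are excluded with a warning.

## Difference scaling

Quadruple MLDS: the probability of judging pair (a, b) more different
than (c, d) is `Φ(((ψ_b − ψ_a) − (ψ_d − ψ_c))/σ)` with `ψ₁ = 0, ψₙ = 1`
anchored and σ estimated (log-parameterized, BFGS). The quadruple rather
than triad protocol is implemented as the common default. σ can
optionally be held fixed: under signal-free (guessing) data the
likelihood is flat — any scale fits once σ → ∞ — so the textbook
null-structure property (guessing ⇒ linear scale) only holds with σ
pinned, and the tests exercise it that way. `equal_step_levels` projects
the fitted scale onto monotone values (isotonic regression, since
sampling noise can produce local dips), rescales to [0, 1], and inverts
by linear interpolation to place n physical levels at equal perceptual
steps; a flat scale is a hard error.

## Matching analysis

Matches live on a 7 × 7 albedo × gloss lattice (49 materials) whose steps
are treated as perceptually equal, so errors and distances are computed
directly in lattice units. The matching error is matched − true
(overestimation positive). Three conditions: match albedo with gloss
pre-set correctly, match gloss with albedo pre-set, match both. The
joint-error prediction takes, per material × filter cell, the Euclidean
norm of the two single-condition mean errors as the predicted
displacement and the distance from the true material to the mean joint
match as observed, then regresses observed on predicted (unweighted OLS;
with 2 albedos × 2 gloss levels × 4 filters this gives 16 cells, df = 14)
and tests the slope against 1 via its standard error. A perfect fit has
zero residual variance, where the slope SE is numerically 0; that case is
detected and reported as t = 0 (slope 1) rather than a 0/0 artifact. A
response set with no displacement anywhere is reported as a flagged
degenerate regression (slope 0, r 0), not an exception. Paired t-tests
guard the zero-variance case the same way. Repeated-measures ANOVA is
deliberately not reimplemented; the tidy per-trial error table is the
export surface for standard ANOVA tooling.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the photometry of rendered scenes:

- **Conjoint design**: every unordered pair of the stimulus grid exactly
  once per repetition (C(16, 2) = 120 pairs, 480 trials at 4 repetitions);
  left/right assignment randomized per trial under the run seed. No
  position-bias term is modelled. How the original counterbalancing was
  done is unknowable from the design counts alone; randomization is the
  recorded default.
- **Conjoint responses**: one Gaussian draw on the decision difference,
  `P(left) = Φ(Δ/σ)` — noise on the comparison, not per stimulus. The
  default cohort truth is additive with ψᵍ = (0, 1, 2, 3),
  ψʳ = (0, −0.2, −0.4, −0.6), σ = 1: a strong gloss signal with a lighter
  layer reducing perceived gloss by a fraction of the gloss range — an
  effect size at which the independent model is rejected for most
  simulated observers while the additive model is retained.
- **Matching responses**: target + per-filter bias + Gaussian noise,
  rounded half-away-from-zero and clipped to the 1..7 lattice (observers
  chose from a discrete set). Default biases fall with the layer's
  transmittance — gloss bias (1.5, 1.0, 0.6, 0.3) and albedo bias
  (0.8, 0.5, 0.2, 0.1) across α = (0.2, 0.4, 0.6, 0.8), noise SD 0.6 —
  so the lowest-contrast image carries the most positive gloss error,
  reproducing the qualitative error-vs-contrast pattern. Joint-condition
  errors are additive by construction, so the prediction regression sits
  near slope 1 in these simulations.
- **Images**: a shaded circular blob (diffuse level = albedo) on an
  8 × 8-check board, with seeded Gaussian highlights whose amplitude
  grows with the gloss parameter; 128 × 128 default. This yields
  realistic-enough luminance histograms and contrasts for the metelli
  diagnostics but makes no claim to BRDF or shape realism — passing tests
  says the analysis chain is correct under its own assumptions, not that
  those assumptions hold for any particular rendered or photographed
  stimulus set.

All generators take explicit integer seeds, draw from private
`numpy.random.Generator` streams, and are bit-reproducible.

## Problem sizes and numerics

Recovery checks use 40 repetitions (4800 trials) for conjoint scales and
1000 quadruples for difference scaling; likelihood-ratio calibration uses
1000 null replicates of the full 480-trial session (empirical type-I rate
≈ 0.04–0.06 at nominal 0.05). The end-to-end runs mirror the study shape:
8 observers, 480 trials each for the paired-comparison experiment; 8
targets × 4 layers × 3 conditions × 3 repetitions per observer for
matching. Brute-force oracles back the optimizers on toy problems: an
exhaustive parameter-lattice search (0.05 step, refined to 0.002 near the
optimum — the continuous optimum generically falls between coarse lattice
points) matches the fitted log-likelihood to 1e-3 on 2 × 2 conjoint and
3-level difference-scaling problems.

## Known limitations

- No lapse-rate or position-bias parameters in the observer models.
- No bootstrap or Bayesian uncertainty on scales; spread is SEM across
  observers only.
- The full model needs every stimulus cell observed; partial designs are
  rejected as under-identified rather than fitted with constraints.
- Chromatic (3-channel) transparency is out of scope; RGB input is
  reduced to luminance first.
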