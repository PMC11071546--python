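# Methods

## Setting

A Bayesian binary classifier has been fitted once on the full data
𝒟 = {(xᵢ, yᵢ)}ᵢ₌₁ⁿ, leaving a matrix of posterior draws θ₁…θ_s. The
goal is every observation's LOO posterior expectation — chiefly the LOO
predictive probability p̂_loo,i = E_{θ|𝒟⁽⁻ⁱ⁾}[σ(μᵢ(θ))] and the log
predictive density elpd_i = log E_{θ|𝒟⁽⁻ⁱ⁾}[ℓ(θ|dᵢ)] — without
refitting. Since π(θ|𝒟⁽⁻ⁱ⁾)/π(θ|𝒟) ∝ 1/ℓ(θ|dᵢ), self-normalized
importance weights ν_ik ∝ 1/ℓ(θ_k|dᵢ) give consistent estimators; the
package aggregates them into LOO-IC = −2 Σᵢ elpd_i and threshold-sweep
ROC/PRC curves with trapezoidal AUROC and step-wise AUPRC.

Supported models are sigmoidal: p(y=1|x,θ) = σ(μ(θ,x)) with

- logistic regression, μ = xᵀβ;
- a one-hidden-layer ReLU network, μ = W₂·relu(W₁x) + b₂, parameters
  flattened as [W₁ row-major, W₂, b₂]; the first-layer bias is absorbed
  into W₁ via a unit covariate component.

Priors are pluggable through `log_density`/`grad_log_density`; an
independent Gaussian N(0, τ²) and an independent Student-t (a
simplified heavy-tailed shrinkage prior standing in for hierarchical
shrinkage families whose latent scales are not carried in the draw
matrix) ship with the package.

## Tail diagnostic and smoothing

The distribution of the largest M importance ratios is modeled by a
generalized Pareto distribution fitted with the Zhang–Stephens
profile-posterior point estimate, with the shape weakly regularized
toward 0.5 (10 pseudo-observations) for small-sample stability. The
tail size is M = ⌈min(0.2·s, 3·√s)⌉, the threshold the (s−M)-th order
statistic. Shape estimates k̂ > 0.7 mark the importance sampler as
unreliable. Pareto smoothing replaces the M tail ratios with the rank
quantiles (j − ½)/M of the fitted distribution, capped at the raw
maximum, then renormalizes. The fit precedes the replacement — the only
order consistent with replacing tail weights *by* fitted quantiles.
The cap guarantees the largest unnormalized ratio never increases;
after renormalization mass can shift toward the maximum (the bulk is
unchanged while the tail shrinks), which is expected behavior.
Degenerate tails (constant weights) report k̂ = −∞ and are treated as
stable: constant weights are the importance sampler's best case.
Smoothing is applied to raw 1/ℓ ratios and to post-transformation
ratios alike; fewer than 25 draws skip smoothing.

## Transformations

All transformations are perturbative bijections T(θ) = θ + h·Q(θ).

**Partial moment matching.** With ν the smoothed self-normalized raw
weights, θ̄ and v the plain draw mean and componentwise variance
(centered at θ̄), θ̄_w and v_w their ν-weighted counterparts:

- PMM1: φ = θ + h̄(θ̄_w − θ̄); a translation, log-Jacobian 0.
- PMM2: φ = θ + h̄(√(v_w/v)∘(θ − θ̄) + θ̄_w − θ); a diagonal affine map
  with per-draw log-Jacobian Σ_α log|1 + h̄(√(v_{w,α}/v_α) − 1)|.
  Non-positive diagonal factors raise a non-bijectivity error, which
  the pipeline records and skips.

h̄ = 1 reproduces the classical MM1/MM2 moment matches (implemented by
delegation, evaluated without any split-sampling scheme). Components
with zero draw variance pass through all transformations unchanged.

**Gradient-flow steps.** For sigmoidal models the KL- and
variance-descent flows reduce to

    Q = (−1)^y · π̃(θ|𝒟) · e^{c·μᵢ(θ)(1−2y)} · ∇μᵢ(θ),   c = 1 (KL), 2 (Var),

with π̃ the *unnormalized* posterior — the unknown evidence is absorbed
into the step size. The LL baseline uses Q = (σ(μᵢ) − y)∇μᵢ. Q is
carried as (sign, log-magnitude, direction): the density factor
overflows double precision on misclassified points, so the step-size
ratio and the realized step h·Q are formed in log space and
exponentiated last. A test asserts that adding any constant to the log
posterior leaves φ and the log-Jacobians unchanged.

**Step size.** h = h̄ · min_{k,α} sd_α / |Q(θ_k)_α| with sd the plain
marginal standard deviation of the draws (the only posterior available
before adaptation; ddof = 1). Every component of every draw therefore
moves at most h̄ posterior standard deviations, and the binding
component moves exactly h̄ — exactly in exact arithmetic, to a few ulp
in floating point, since the ratio is reassembled by multiply-divide.
If every Q entry vanishes the transformation degenerates to the
identity and is recorded as such.

**Jacobians.** The log-determinant of ∇T = I + h∇Q:

- *Logistic regression, exact.* ∇Q = A·(g wᵀ) is rank one
  (g = x, w = ∇log π̃ + c(1−2y)x, A the scalar density factor), so
  log 𝒥 = log|1 + h·A·xᵀw|. For LL the same algebra gives
  log|1 + h·σ′(μ)·xᵀx|.
- *One-hidden ReLU, exact.* ∇Q = A(H + g wᵀ) with H = ∇∇μ. H couples
  W₁ row k with (W₂)_k through u_k = relu′((z₁)_k)·x, giving 2d
  eigenpairs λ_k± = ±[relu′((z₁)_k)·Σⱼxⱼ²]^{1/2} with eigenvectors
  (u_k/(√2|u_k|), ±e_k/√2) in the (W₁-row, W₂) slots; dead units
  contribute zero. Since I + h∇Q acts as the identity on the orthogonal
  complement of S = span(eigenvectors, g, w), the determinant is that
  of the dense restriction to S (dimension ≤ 2d + 2), computed by QR
  projection and `slogdet`. With all units dead this collapses to the
  rank-one formula.
- *Generic first order.* log|1 + h∇·Q| with ∇·Q = A·wᵀg (the mean
  functions of both model families have identically zero Laplacian).
  Its truncation error against the exact rules is O(h²) — except for
  logistic regression, where the rank-one structure makes
  det(I + h∇Q) = 1 + h·tr(∇Q) exact and the two rules coincide
  identically. The convergence-order test therefore measures the slope
  on the ReLU net and asserts exact agreement on logistic regression.

ReLU′(0) := 0 (left-continuous step convention); the kink set has
measure zero under continuous posteriors.

## Transformed weights and the adaptation loop

After a transformation, the importance ratio for draw k is

    log η_k = log 𝒥_T(θ_k) − log ℓ(φ_k|dᵢ) + [log π̃(φ_k|𝒟) − log π̃(θ_k|𝒟)],

with the posterior ratio evaluated exactly as the prior ratio plus all
n likelihood ratios (the form rederived from the change-of-variables
integrand and validated against a quadrature oracle; desk-scale n makes
data subsampling unnecessary). With T = identity this reduces
bit-exactly to the raw ratios, so the pipeline contains plain PSIS-LOO
as a special case. For draws from a variational approximation q̂ the
corrected weights log χ_k = log 𝒥 − log q̂(θ_k) + log π(φ_k) +
Σ_{j≠i} log ℓ(φ_k|dⱼ) replace the posterior-ratio form.

Per observation: compute raw k̂; if ≤ 0.7, done (winner "raw" — a
transformation is never attempted even if it could do better). Else
scan methods in order PMM1, PMM2, KL, Var, LL (cheapest first — the
moment matches need no model gradients) across the full h̄ grid,
re-smoothing and re-estimating k̂ each time, stopping at the first
success; an exhaustive mode instead reports the global k̂ minimizer.
Failed observations keep the minimizing combination's estimates and are
counted as needing a refit. No multiplicity correction is applied to
the (method, h̄) scan: success-if-any is the operating definition of
adaptation. Records are independent across observations, so the report
is invariant to observation order. Metrics use the winner's weights
with likelihoods and predictive probabilities evaluated at the
transformed draws.

## Synthetic data and truth channels

`generate_classification` draws i.i.d. standard-normal covariates
(optionally one equicorrelation block mimicking microarray
multicollinearity), a sparse coefficient vector with alternating-sign
entries of magnitude `effect_size`, and Bernoulli labels through the
logistic link; it is a pure function of its seed. The canonical
unstable regime — n = 50, p_x = 300, 5 effects of size 2, s = 1000
draws, Student-t(3, 0.5) shrinkage prior — was chosen as the smallest
configuration that reliably (≥ 95% of seeds) yields observations with
raw k̂ > 0.7 while a full run with the 11-point h̄ grid completes in
seconds; it preserves the p ≫ n character of the motivating problems
without chasing any particular dataset's scale.

Truth channels: a deterministic quadrature grid (p ≤ 2; MAP-centered,
±8 Laplace sd, 201 points per dimension, midpoint rule) treated as
exact, and an adaptive random-walk Metropolis sampler (MAP-started,
proposal scale adapted toward 23% acceptance and componentwise scales
from warmup moments, both frozen before retention so detailed balance
holds). `brute_force_loo` refits per fold through either channel;
comparisons use 3 combined Monte-Carlo standard errors, with the
self-normalized IS standard error √(Σ w_k²(f_k − f̂)²) on the IS side.

What the generator does **not** emulate: real covariate correlation
structure beyond one equicorrelation knob, hierarchical-shrinkage
posterior geometry (funnels), and MCMC pathologies such as divergences.
Passing tests demonstrate correctness of the weighting, transformation
and Jacobian machinery under realistic heavy-tailed weight regimes, not
performance claims on any particular real dataset.

## Numerical conventions

- All densities and weights live in log space until self-normalization;
  log-sigmoid uses `-log1p(exp(-|μ|))` style stable forms.
- log|1 + s·eᵗ| is computed via `logaddexp` (s > 0) or `log|expm1(t)|`
  (s < 0); an exact cancellation (−∞) raises a degenerate-map error,
  which the adaptation loop records and skips.
- Draw CSVs are written with 17 significant digits and parsed with
  round-trip float precision, making read/write the identity.
- Per-observation child seeds derive from (global seed, observation,
  method label) via `SeedSequence`, independent of iteration order.

## Limitations

- Model-dependent by design: requires μ, ∇μ, prior gradient. Exact
  Jacobians cover logistic regression and one-hidden-layer ReLU nets;
  deeper networks fall back to the first-order rule.
- Single gradient-flow step only; no multi-step integration or learned
  transformations.
- The quadrature truth channel stops at two parameters; MH truths carry
  Monte-Carlo error and are thinned toward, but not guaranteed,
  independence.
- The MH sampler is a convenience for synthetic studies, not a
  replacement for a production sampler in high dimensions.
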