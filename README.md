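# adaloo — adaptive importance-sampling LOO for Bayesian classifiers

Leave-one-out (LOO) cross-validation is the gold-standard estimate of a
Bayesian model's out-of-sample performance, but refitting the model *n*
times is often prohibitively expensive. Importance sampling avoids the
refits: the full-data posterior π(θ|𝒟) serves as the proposal for every
leave-one-out posterior π(θ|𝒟⁽⁻ⁱ⁾), with self-normalized weights
proportional to 1/ℓ(θ|dᵢ). In few-observations / many-predictors
problems (microarrays, other n ≪ p designs) these weights are heavy
tailed and the estimator breaks down — the fitted generalized-Pareto
tail shape k̂ of the weights exceeds 0.7 for many observations, even
after Pareto smoothing (PSIS).

`adaloo` repairs those observations **without refitting** by adapting
the proposal with perturbative bijections

    T(θ) = θ + h·Q(θ),   0 < h ≪ 1,

applied draw-wise to the posterior sample, with the change-of-variables
weights

    η_k = 𝒥_T(θ_k) · (1/ℓ(φ_k|dᵢ)) · π(φ_k|𝒟)/π(θ_k|𝒟),  φ_k = T(θ_k).

Four transformation families are provided:

- **PMM1 / PMM2** — partial moment matching: move the sample a fraction
  h̄ of the way toward the importance-weighted mean (PMM1) or mean and
  componentwise variance (PMM2); h̄ = 1 recovers the classical MM1/MM2
  moment matches.
- **KL** — a single forward-Euler step along the gradient flow that
  descends the KL divergence to the LOO target:
  Q = (−1)^y π(θ|𝒟) e^{μ(1−2y)} ∇μ for sigmoidal models.
- **Var** — the analogous step descending the variance of the IS
  estimator of the complement outcome probability (same form with the
  exponent doubled).
- **LL** — a comparison baseline stepping down the left-out point's
  log-likelihood gradient.

The step size is capped at h̄ posterior standard deviations in every
parameter component, and an 11-point grid h̄ = 4⁻ʳ, r = 0…10 is scanned
per method; adaptation succeeds as soon as *any* (method, h̄) pushes the
post-transformation k̂ below threshold. Jacobian determinants are exact
for logistic regression (rank-one formula) and for one-hidden-layer
ReLU networks (closed-form Hessian eigenstructure plus a small dense
determinant), and first-order, log|1 + h ∇·Q|, otherwise.

## Worked example

```python
from adaloo import psis, run_loo
from adaloo.sample_io import RunConfig
from adaloo.synthetic import unstable_regime_problem

data, draws, model, beta = unstable_regime_problem(seed=0)
report = run_loo(draws, model, data, RunConfig(seed=0))
```

Running `python examples/01_diagnose_and_adapt.py` (the script around
the snippet above) prints:

```
observations with raw k-hat > 0.7: 43 of 50
winners by method: {'PMM1': 43, 'raw': 7}
failures after adaptation (would need a refit): 0
LOO AUROC = 1.000   LOO-IC = 10.7
```

43 of 50 observations have unreliable raw importance weights; the
partial moment match stabilizes all of them (k̂ ≤ 0.7), so the LOO
predictive probabilities — and the AUROC and LOO-IC computed from them
— are trustworthy with zero refits. `examples/02_validate_against_refits.py`
confirms the estimates against brute-force per-fold refits on a small
problem (max |IS-LOO − refit| = 0.0024 at 4000 draws), and
`examples/03_transformations_up_close.py` dissects a single observation
across methods and step sizes.

A thin CLI wraps the same pipeline:

```bash
adaloo simulate --regime unstable_npp --seed 7 --out-data data.csv --out-draws draws.csv
adaloo diagnose --draws draws.csv --data data.csv
adaloo run --draws draws.csv --data data.csv --model lr --prior shrinkage --out report.json
```

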