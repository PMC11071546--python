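"""Diagnose unstable LOO importance weights and stabilize them.

Builds a scaled-down n << p classification problem (n=50 observations,
300 predictors, 5 true effects), samples the logistic-regression
posterior, and runs the adaptive LOO pipeline.  The raw 1/likelihood
importance weights are heavy tailed for most observations (Pareto
k-hat > 0.7, meaning plain importance sampling is unreliable there);
the perturbative transformations repair almost all of them without a
single model refit.
"""

from collections import Counter

from adaloo import psis, run_loo
from adaloo.sample_io import RunConfig
from adaloo.synthetic import unstable_regime_problem

data, draws, model, beta = unstable_regime_problem(seed=0)

loglik = model.loglik_all(draws.draws, data)
raw_khat = [
    psis.khat_of(psis.raw_loo_log_ratios(loglik[:, i])) for i in range(data.n_obs)
]
n_unstable = sum(k > 0.7 for k in raw_khat)
print(f"observations with raw k-hat > 0.7: {n_unstable} of {data.n_obs}")

report = run_loo(draws, model, data, RunConfig(seed=0))
winners = Counter(r.winner for r in report.per_obs)
print(f"winners by method: {dict(winners)}")
print(f"failures after adaptation (would need a refit): {report.n_failed}")
print(f"LOO AUROC = {report.auroc:.3f}   LOO-IC = {report.loo_ic:.1f}")
# Each stabilized observation now has a trustworthy LOO predictive
# probability; the AUROC above is the honest out-of-sample estimate.
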