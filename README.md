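# mwpffc

Classical and Bayesian inference for the three-parameter **modified Weibull
distribution (MWD)** under **progressive first-failure censoring (PFFC)** —
a life-testing design common in biomedical survival analysis and
reliability studies, where testing every unit to failure is too slow or
too costly.

## The model and the design

The MWD is the lifetime law with survival function

    S(t) = exp{ λβ (1 − e^{(t/β)^α}) },    α, β, λ > 0,

whose hazard is increasing for α ≥ 1 and bathtub-shaped for α < 1 (minimum
at t\* = β((1−α)/α)^{1/α}) — a natural candidate for graft-survival data
with high early failure rates. At λ = 1 it reduces to the exponential-power
law; as β → ∞ it degenerates to an ordinary Weibull, a boundary that
matters for small-sample estimation (see `docs/methods.md`).

Under PFFC, n groups of k units are tested; at the i-th observed first
failure, R_i of the surviving groups are withdrawn, leaving m ordered
first-failure times x_1 ≤ … ≤ x_m. The log-likelihood is

    ℓ = m ln(αλ) + (α−1) Σ ln(x_i/β) + Σ z_i − kλβ Σ (R_i+1)(e^{z_i} − 1),
    z_i = (x_i/β)^α,

with the closed-form profile λ̂(α, β) = m / (kβ Σ (R_i+1)(e^{z_i} − 1)).

The package provides:

* the MWD kernel (pdf/cdf/sf/hazard/quantile/sampling) — `mwpffc.distribution`;
* scheme construction (SC1/SC2/SC3) and exact PFFC sample generation via the
  progressive-uniform construction through the transformed CDF
  1 − (1−F)^k — `mwpffc.censoring`;
* MLE with observed-information Wald intervals and delta-method intervals
  for S(t), h(t), r(t) — `mwpffc.mle`;
* Lindley-approximation Bayes estimates under squared-error (SELF) and
  general-entropy (GELF) loss with independent gamma priors — `mwpffc.lindley`;
* a Metropolis-within-Gibbs sampler (gamma conditional for λ, random-walk
  M-H for α and β), posterior point estimates and percentile/HPD credible
  intervals — `mwpffc.mcmc`;
* a Monte-Carlo study harness tabulating MSE/MAE, interval length and
  coverage across schemes and sample sizes — `mwpffc.study`;
* the renal-transplant case study with a Kolmogorov–Smirnov fit check —
  `mwpffc.application`;
* a `mwpffc` command-line tool (`sample`, `fit`, `bayes`, `simulate`, `gof`).

## Worked example

```python
import numpy as np
import mwpffc as mw

# the censored renal-transplant subsample: n=20 groups of k=5, m=10 failures
s = mw.build_pffc_subsample()
fit = mw.fit_mle(s)
print(fit.params_hat)
# MWDParams(alpha=0.4052338891830415, beta=3.8918394867948316, lam=0.06353392422182827)
print(round(fit.loglik, 4), mw.wald_ci(fit)["alpha"])
# -20.4703 (0.10190304909636971, 0.7085647292697133)

# complete-data fit of all 100 graft survival times + goodness of fit
comp = mw.fit_mle(mw.application.complete_sample())
print(mw.ks_test(mw.load_renal().times, comp.params_hat))
# (0.09265793965848013, 0.3570929318917643)
```

The fitted hazard shape α̂ < 1 says the graft-failure rate is bathtub-like:
very high immediately after transplant, falling, then slowly rising. The
K-S distance 0.093 (p = 0.36) indicates the MWD fits the complete data
well. Bayes estimates follow the same pattern:

```python
from mwpffc import ChainConfig, GammaPriors, run_chain, posterior_estimate
flat = GammaPriors(*[1e-4] * 6)            # near-flat gamma priors
chain = run_chain(s, flat, ChainConfig(n_iter=12000, burn_in=2000, seed=1))
print(round(posterior_estimate(chain, "alpha"), 4))
# 0.2381  (the posterior is very diffuse for m=10; see docs/methods.md)
```

## Layout

```
src/mwpffc/        library (distribution, censoring, mle, lindley, mcmc,
                   study, application, cli)
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    model, algorithms, numerical choices, limitations
```
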