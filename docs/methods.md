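# Methods

## Model

The modified Weibull distribution (MWD) has

    f(x) = λα (x/β)^{α−1} exp{ (x/β)^α + λβ(1 − e^{(x/β)^α}) },
    F(x) = 1 − exp{ λβ (1 − e^{(x/β)^α}) },        x ≥ 0,  α, β, λ > 0.

β carries the time units, λβ is the dimensionless exponent scale, and α
alone controls the hazard shape: increasing for α ≥ 1, bathtub with an
interior minimum at t\* = β((1−α)/α)^{1/α} for α < 1. Rescaling time by c
maps (α, β, λ) to (α, cβ, λ/c); the fit respects this invariance.

Two degenerate limits matter in practice:

* **λ = 1** gives the exponential-power law (noted, not separately
  implemented).
* **β → ∞ with λβ^{1−α} fixed** gives an ordinary two-parameter Weibull,
  because e^{z} − 1 → z when z = (x/β)^α → 0 and the survival function
  collapses to exp(−λβ^{1−α} x^α). The MWD therefore contains the Weibull
  on the *boundary* of its parameter space. Whenever a finite sample looks
  Weibull-like, the likelihood rises along a nearly flat ridge toward
  β = ∞ and the maximizer escapes. This single fact drives most of the
  numerical choices and the honest limitations below.

## Censoring design and sampling

Under progressive first-failure censoring (PFFC), n groups of k units are
tested and at the i-th observed first failure R_i surviving groups are
withdrawn (ΣR_i = n − m). The first-failure time of a group of k follows
the transformed law F\*(x) = 1 − (1 − F(x))^k, so a PFFC sample from the
MWD is a progressively type-II censored sample from F\*. Generation is
exact: with W_i ~ U(0,1),

    V_i = W_i^{1/(i + R_m + … + R_{m−i+1})},
    U_i = 1 − V_m V_{m−1} ⋯ V_{m−i+1},
    X_i = F^{-1}( 1 − (1 − U_i)^{1/k} ),

which the tests check against two closed-form laws: X_1 is the minimum of
nk i.i.d. units, and the k = 1, R = 0 design reduces to a sorted complete
sample. Group membership is not simulated; only first-failure times enter
the likelihood. Standard removal layouts: SC1 (all removals at the first
failure), SC2 (middle; an odd n−m with even m uses a floor/ceil split with
a warning), SC3 (last).

## Likelihood, score, information

With z_i = (x_i/β)^α and weights w_i = R_i + 1:

    ℓ = m ln(αλ) + (α−1) Σ ln(x_i/β) + Σ z_i − kλβ Σ w_i (e^{z_i} − 1).

The censoring term is *always* evaluated through `expm1`: the algebraically
equivalent form knλβ − kλβ Σ w_i e^{z_i} subtracts two nearly equal huge
numbers on the large-β ridge and loses all significance. The analytic
score is unit-tested against central finite differences of ℓ at 1e−6
relative tolerance on random parameter/sample pairs — this is the guard
against transcription errors in the derivative algebra. ∂ℓ/∂λ = 0 has the
closed-form solution λ̂(α, β) = m / (kβ Σ w_i (e^{z_i} − 1)), used both to
reduce the optimization to two dimensions and as a consistency check of
the joint optimum. ∂²ℓ/∂λ² = −m/λ² exactly, and is asserted to machine
precision.

**Optimization.** Nelder-Mead on (ln α, ln β) with λ profiled out, run
from three deterministic starts (β near the data median, near max(x), and
beyond it) inside a soft box |ln β − ln x̄| ≲ 4 (quadratic penalty outside),
followed by one unconstrained BFGS polish of the best candidate in
log-parameters with the analytic gradient. The box exists because the
simplex otherwise slides down the flat Weibull ridge and terminates on a
*worse* plateau than the interior maximum. A fit is flagged `boundary`
when β̂ leaves [min(x)/100, 100·max(x)]; such maximizers are genuine but
their (β, λ) components are not meaningfully identified.

**Observed information.** Minus the Hessian of ℓ, by central differences
of the analytic score (default, relative step 1e−5) or by complex-step
differentiation of the score (exact to machine precision; used wherever
third derivatives are needed). Wald intervals are untruncated by default
(a truncation flag exists); delta-method variances for S(t), h(t), r(t)
use numerically differentiated gradients sandwiched with the inverse
information, validated against a parametric-bootstrap cloud.

## Bayes estimation

Independent Gamma(a_i, b_i) priors on (α, β, λ); all-zero hyperparameters
give the Jeffreys-type 1/(αβλ) prior. Two estimators:

* **Lindley approximation.** The posterior expectation of w(θ) is expanded
  to second order around the MLE:
  E[w] ≈ w + Σ w_i a_i + a₄ + a₅ + ½ Σ_k (Σ_{ij} ℓ_{ijk} τ_{ij})(Σ_l τ_{kl} w_l),
  with τ the inverse negative likelihood Hessian, ρ the log-prior gradient,
  a_i = Σ_j ρ_j τ_{ij}, a₄ = Σ_{i<j} w_{ij} τ_{ij}, a₅ = ½ Σ_i w_{ii} τ_{ii}.
  The ½ on the third-derivative term is part of Lindley's expansion and is
  kept (its validity is checked by agreement with the MCMC posterior mean
  to ~1% at m = 200–500). Third derivatives come from central differences
  of the complex-step Hessian; w-derivatives from central differences.
  Under GELF the target is w = g^{−ε} followed by the outer power
  (·)^{−1/ε}; at ε = −1 both maps are the identity and the GELF estimate
  equals the SELF estimate bit-for-bit. Lindley yields point estimates
  only, no intervals.

* **Metropolis-within-Gibbs.** λ has an exact gamma full conditional,
  Gamma(m + a₃, b₃ + kβ Σ w_i (e^{z_i} − 1)); α and β are updated by normal
  random-walk M-H with proposal scales defaulting to the Wald standard
  errors (fallback: 10% of the current value when the information matrix
  is not positive definite). The chain starts at the MLE; nonpositive
  proposals have zero target density. Each printed conditional kernel is
  tested to equal the joint log posterior up to an additive constant at
  1e−10 — the same anti-typo guard as for the score. Point estimates:
  post-burn-in mean (SELF) or [mean(draws^{−ε})]^{−1/ε} (GELF). Intervals:
  equal-tail percentile over sorted draws with order-statistic indices
  (⌊γN′⌋, ⌈(1−γ)N′⌉) so that γ = 0.025 yields the conventional 95% level;
  an HPD (shortest-window) variant is available but non-default. The
  sampler is validated against brute-force 3-D grid quadrature of an m = 3
  toy posterior (agreement within Monte-Carlo error) and by a
  detailed-balance occupancy check of the M-H kernel on a two-bin target.

## Monte-Carlo study

Cells are (n, m) × scheme; per replicate a PFFC sample is generated at the
true parameters and every requested estimator is run. Default study
conditions follow the published experiment: truth (α, β, λ) = (1, 0.1, 2),
k = 2, 1000 replicates, gamma priors a_i = 1, b_i = 2 for the Bayes
estimators (the case study instead uses near-flat a_i = b_i = 10⁻⁴), GELF
at ε = ±1. Replicate r of cell c is seeded from (master seed, c, r), so
results are order-independent and exactly reproducible. Replicates whose
fit fails to converge or is boundary-flagged are excluded and counted
(`n_failed`; ~6% at (30,15), <1% at (90,75)). MCMC inside the study uses a
reduced default chain (3000/500) for desk-scale runtime, overridable to
the full 12000/2000.

Both the mean squared error and the mean absolute error are reported for
every point estimator. The historically tabulated dispersion values for α̂
correspond to the *mean absolute error* (they match it across every cell
we checked, while the squared-error numbers are ~40% smaller), so tables
pivot on MAE by default; both metrics are in the long-format results.

## Case study

The 100 renal graft survival times ship as an embedded, checksum-verified
fixture, together with the censored subsample (n = 20 groups of k = 5,
m = 10, R = 2,1,1,2,1,1,1,1,0,0). Complete-data fitting is the k = 1,
R = 0, m = n special case of the same PFFC likelihood — one code path. The
K-S test uses the asymptotic Kolmogorov p-value by default (exact optional)
and, as is conventional for this procedure, ignores the effect of
parameter estimation (no Lilliefors correction). The complete-data fit
gives (α̂, β̂, λ̂) = (0.536, 0.509, 0.347) and (D, p) = (0.0927, 0.357).
A seeded regrouping generator produces fresh censored subsamples; the
original random grouping is not recoverable, so the printed subsample is
kept verbatim as the reference input.

## Known limitations

* **β is boundary-fragile.** Because the Weibull sits on the β → ∞
  boundary, small-sample maximum-likelihood estimates of β and λ have
  heavy tails (occasionally escaping entirely), their MSEs are
  outlier-dominated, and Wald intervals for α undercover: measured 95%
  coverage for α at (n, m) = (90, 75) is ≈ 0.91, approaching the nominal
  level only slowly with n. Coverage for λ is nominal. Profile-likelihood
  or bootstrap intervals would be the remedy; they are out of scope here.
* **Lindley needs information.** At m ≲ 15 on this model the second-order
  corrections are of the same magnitude as the estimates (they can even
  push λ̂ negative on the diffuse renal-subsample posterior); the
  approximation is only trustworthy when the likelihood concentrates
  (validated at m ≥ 200). The MCMC estimator has no such restriction.
* **Near-flat priors on tiny censored samples** produce an extremely
  diffuse, ridge-shaped posterior (the renal subsample's 95% credible
  interval for β spans two orders of magnitude); posterior means of α are
  then sensitive to mixing and should be read with the credible intervals,
  not alone.
* The synthetic-data generator draws exactly from the assumed model; real
  survival data bring ties, rounding, covariates and model misspecification
  that these tests do not probe. Passing the suite demonstrates correctness
  of the algorithms under the model, not adequacy of the model for any
  particular dataset.
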