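"""Metropolis-within-Gibbs sampling of the joint posterior.

Under independent gamma priors the full conditional of ``lam`` is itself a
gamma law,

    lam | alpha, beta, data ~ Gamma(m + a3,
        b3 + k*beta * sum (R_i+1) * (exp[(x_i/beta)**alpha] - 1)),

while the conditionals of ``alpha`` and ``beta`` have no standard form and
are updated by normal random-walk Metropolis steps.  The chain starts at
the MLE and defaults its proposal scales to the Wald standard errors;
nonpositive proposals carry zero target density and are rejected, which is
the plain M-H kernel on the positive half-line.

Point estimates follow from the post-burn-in draws (SELF = mean, GELF =
inverse-eps power of the mean of draws**(-eps)); equal-tail percentile
credible intervals come from the sorted draws, with an optional
highest-posterior-density variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .censoring import PFFCSample
from .distribution import MWDParams, sf, hrf, ihrf
from .lindley import GammaPriors, LossSpec
from .mle import MLEFit, fit_mle, loglik

__all__ = [
    "ChainConfig", "Chain", "lambda_conditional", "log_cond_alpha",
    "log_cond_beta", "log_joint_posterior", "metropolis_step", "run_chain",
    "posterior_estimate", "credible_interval",
]

_COLS = {"alpha": 0, "beta": 1, "lam": 2, "S": 3, "h": 4, "r": 5}


@dataclass(frozen=True)
class ChainConfig:
    """Sampler settings: length, burn-in, proposal scales, seed, t for S/h/r."""

    n_iter: int = 12000
    burn_in: int = 2000
    proposal_sd_alpha: float | None = None  # default: Wald SE of alpha-hat
    proposal_sd_beta: float | None = None
    seed: int = 0
    t_eval: float | None = 1.0  # None skips the S/h/r tracking columns

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        for nm in ("proposal_sd_alpha", "proposal_sd_beta"):
            v = getattr(self, nm)
            if v is not None and v <= 0:
                raise ValueError(f"{nm} must be positive")


@dataclass
class Chain:
    """Posterior draws (columns alpha, beta, lam, S, h, r) plus diagnostics."""

    draws: np.ndarray
    accept_rate_alpha: float
    accept_rate_beta: float
    config: ChainConfig

    def post_burn(self, quantity: str) -> np.ndarray:
        return self.draws[self.config.burn_in:, _COLS[quantity]]


def lambda_conditional(alpha: float, beta: float, s: PFFCSample, priors: GammaPriors):
    """Gamma(shape, rate) spec of the lam full conditional."""
    sc = s.scheme
    w = sc.R_array + 1
    with np.errstate(over="ignore"):
        acc = np.sum(w * np.expm1((s.x / beta) ** alpha))
    rate = priors.b3 + sc.k * beta * acc
    if not np.isfinite(rate) or rate <= 0:
        raise FloatingPointError("lambda-conditional rate overflowed or is nonpositive")
    return sc.m + priors.a3, float(rate)


def log_cond_alpha(alpha: float, beta: float, lam: float, s: PFFCSample, priors: GammaPriors) -> float:
    """Unnormalized log conditional density of alpha (log-density convention:
    -inf outside the support)."""
    if alpha <= 0:
        return -np.inf
    sc = s.scheme
    w = sc.R_array + 1
    with np.errstate(over="ignore"):
        z = (s.x / beta) ** alpha
        v = (
            (sc.m + priors.a1 - 1.0) * np.log(alpha)
            + np.sum(z + alpha * np.log(s.x / beta))
            - sc.k * lam * beta * np.sum(w * np.exp(z))
            - priors.b1 * alpha
        )
    return float(v) if np.isfinite(v) else -np.inf


def log_cond_beta(beta: float, alpha: float, lam: float, s: PFFCSample, priors: GammaPriors) -> float:
    """Unnormalized log conditional density of beta."""
    if beta <= 0:
        return -np.inf
    sc = s.scheme
    w = sc.R_array + 1
    with np.errstate(over="ignore"):
        z = (s.x / beta) ** alpha
        v = (
            (priors.a2 - 1.0) * np.log(beta)
            + np.sum(z + (alpha - 1.0) * np.log(s.x / beta))
            - lam * beta * sc.k * np.sum(w * np.expm1(z))
            - priors.b2 * beta
        )
    return float(v) if np.isfinite(v) else -np.inf


def log_joint_posterior(theta, s: PFFCSample, priors: GammaPriors) -> float:
    """Unnormalized log posterior: corrected log-likelihood + log prior."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        return -np.inf
    p = MWDParams.from_array(theta)
    return loglik(p, s) + priors.log_prior(theta)


def metropolis_step(x: float, logp, sd: float, rng: np.random.Generator):
    """One normal random-walk M-H update; returns (new state, accepted)."""
    prop = rng.normal(x, sd)
    lp_cur = logp(x)
    if not np.isfinite(lp_cur):
        raise FloatingPointError("non-finite log-density at the current state")
    lp_prop = logp(prop)
    if np.log(rng.uniform()) < lp_prop - lp_cur:
        return prop, True
    return x, False


def run_chain(
    s: PFFCSample,
    priors: GammaPriors,
    cfg: ChainConfig = ChainConfig(),
    fit: MLEFit | None = None,
) -> Chain:
    """Run the Gibbs/M-H sampler initialized at the MLE.

    Per iteration: draw lam from its gamma conditional, then M-H updates of
    alpha and beta; S(t), h(t), r(t) are recorded at ``cfg.t_eval``.
    Identical config and seed give an identical chain.
    """
    if fit is None:
        fit = fit_mle(s)
    rng = np.random.default_rng(cfg.seed)
    a, b, lam = fit.params_hat.as_array()
    se = fit.se
    sd_a = cfg.proposal_sd_alpha
    if sd_a is None:
        sd_a = float(se[0]) if np.isfinite(se[0]) and se[0] > 0 else 0.1 * a
    sd_b = cfg.proposal_sd_beta
    if sd_b is None:
        sd_b = float(se[1]) if np.isfinite(se[1]) and se[1] > 0 else 0.1 * b

    N = cfg.n_iter
    draws = np.empty((N, 6))
    acc_a = acc_b = 0
    t = cfg.t_eval
    for j in range(N):
        shape, rate = lambda_conditional(a, b, s, priors)
        lam = rng.gamma(shape, 1.0 / rate)
        a, ok = metropolis_step(a, lambda v: log_cond_alpha(v, b, lam, s, priors), sd_a, rng)
        acc_a += ok
        b, ok = metropolis_step(b, lambda v: log_cond_beta(v, a, lam, s, priors), sd_b, rng)
        acc_b += ok
        if t is None:
            draws[j] = (a, b, lam, np.nan, np.nan, np.nan)
        else:
            p = MWDParams(a, b, lam)
            draws[j] = (a, b, lam, sf(t, p), hrf(t, p), ihrf(t, p))
        if j + 1 == cfg.burn_in and cfg.burn_in > 0:
            if max(acc_a, acc_b) < 0.01 * cfg.burn_in:
                warnings.warn(
                    "acceptance rate below 1% during burn-in; consider smaller "
                    "proposal scales or a better starting point", stacklevel=2,
                )
    return Chain(draws=draws, accept_rate_alpha=acc_a / N, accept_rate_beta=acc_b / N,
                 config=cfg)


def posterior_estimate(chain: Chain, quantity: str, loss: LossSpec = LossSpec("SELF")) -> float:
    """Bayes point estimate from the post-burn-in draws under SELF or GELF."""
    d = chain.post_burn(quantity)
    if d.size == 0:
        raise ValueError("empty post-burn-in chain")
    if loss.kind == "SELF":
        return float(np.mean(d))
    eps = loss.epsilon
    return float(np.mean(d ** (-eps)) ** (-1.0 / eps))


def credible_interval(chain: Chain, quantity: str, gamma: float = 0.025, hpd: bool = False):
    """Equal-tail percentile interval from sorted post-burn-in draws.

    Order-statistic convention: (floor(gamma*N'), ceil((1-gamma)*N')) with
    N' the retained length, both clamped to valid range; the printed level
    is 100*(1-2*gamma)%.  ``hpd=True`` instead returns the shortest window
    containing a (1-2*gamma) fraction of the draws.
    """
    d = np.sort(chain.post_burn(quantity))
    np_ = d.size
    if np_ == 0:
        raise ValueError("empty post-burn-in chain")
    if hpd:
        wlen = int(np.ceil((1.0 - 2.0 * gamma) * np_))
        wlen = min(max(wlen, 1), np_)
        widths = d[wlen - 1:] - d[: np_ - wlen + 1]
        i = int(np.argmin(widths))
        return float(d[i]), float(d[i + wlen - 1])
    lo = min(max(int(np.floor(gamma * np_)), 1), np_)
    hi = min(max(int(np.ceil((1.0 - gamma) * np_)), 1), np_)
    return float(d[lo - 1]), float(d[hi - 1])
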