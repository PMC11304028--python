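"""Likelihood inference for PFFC samples from the modified Weibull law.

With observed first-failure times ``x_1 <= ... <= x_m`` under scheme
``(n, m, k, R)`` and ``z_i = (x_i/beta)**alpha``, the log-likelihood (up to
the parameter-free ordering constant) is

    l = m*log(alpha*lam) + (alpha-1)*sum log(x_i/beta) + sum z_i
        + k*n*lam*beta - k*lam*beta * sum (R_i+1) * exp(z_i).

Setting dl/dlam = 0 gives the closed-form profile
``lam(alpha, beta) = m / (k*beta*sum((R_i+1)*(exp(z_i)-1)))``, which reduces
the search to two dimensions before a joint quasi-Newton polish in
log-parameters.  The observed information is the negative Hessian of ``l``,
by central differences of the analytic score (or complex-step, to machine
precision); Wald intervals for the parameters and delta-method intervals
for S(t), h(t), r(t) follow from its inverse.

A caution that shapes several defaults here: as ``beta -> inf`` the MWD
degenerates to an ordinary Weibull, so the likelihood has a flat ridge and
small-sample maximizers escape to that boundary with positive probability.
Fits whose ``beta`` exceeds ``boundary_factor * max(x)`` are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .censoring import PFFCSample
from .distribution import MWDParams, sf, hrf, ihrf

__all__ = [
    "MLEFit", "ReliabilityPoint", "loglik", "score", "profile_lam",
    "fit_mle", "observed_info", "wald_ci", "reliability_point", "delta_ci",
]

_BOUNDARY_FACTOR = 100.0  # beta-hat beyond max(x)*this (or below min(x)/this) is a ridge escape


def _unpack(s: PFFCSample):
    x = s.x
    if np.any(x <= 0):
        raise ValueError("all observed times must be > 0")
    sc = s.scheme
    return x, sc.R_array + 1, sc.n, sc.m, sc.k


def loglik(p: MWDParams, s: PFFCSample) -> float:
    """Corrected PFFC log-likelihood (ordering constant dropped)."""
    x, w, n, m, k = _unpack(s)
    a, b, lam = p.alpha, p.beta, p.lam
    with np.errstate(over="ignore"):
        v = _loglik_arr((a, b, lam), x, w, n, m, k)
    return float(v) if np.isfinite(v) else -np.inf


def _expm1(z):
    # np.expm1 lacks a complex loop; the exp(z)-1 fallback only serves the
    # complex-step derivative path, where real-part cancellation is harmless
    return np.exp(z) - 1.0 if np.iscomplexobj(z) else np.expm1(z)


def _loglik_arr(theta, x, w, n, m, k):
    """loglik on a raw parameter array; complex-safe for derivative checks.

    The censoring term is written as -k*lam*beta*sum(w*expm1(z)) (identical
    to k*n*lam*beta - k*lam*beta*sum(w*exp(z)) since sum(w) = n) to avoid
    catastrophic cancellation on the large-beta ridge.
    """
    a, b, lam = theta
    z = (x / b) ** a
    return (
        m * np.log(a * lam)
        + (a - 1.0) * np.sum(np.log(x / b))
        + np.sum(z)
        - k * lam * b * np.sum(w * _expm1(z))
    )


def _score_arr(theta, x, w, n, m, k):
    a, b, lam = theta
    z = (x / b) ** a
    L = np.log(x / b)
    E = np.exp(z)
    da = m / a + np.sum(L) + np.sum(z * L * (1.0 - k * lam * b * w * E))
    db = (
        -m * (a - 1.0) / b
        - (a / b) * np.sum(z)
        - k * lam * np.sum(w * _expm1(z))
        + k * lam * a * np.sum(w * E * z)
    )
    dl = m / lam - k * b * np.sum(w * _expm1(z))
    return np.array([da, db, dl])


def score(p: MWDParams, s: PFFCSample) -> np.ndarray:
    """Analytic gradient of :func:`loglik` in (alpha, beta, lam) order."""
    x, w, n, m, k = _unpack(s)
    with np.errstate(over="ignore"):
        g = _score_arr(p.as_array(), x, w, n, m, k)
    return g


def profile_lam(alpha: float, beta: float, s: PFFCSample) -> float:
    """Closed-form zero of dl/dlam at fixed (alpha, beta)."""
    x, w, n, m, k = _unpack(s)
    with np.errstate(over="ignore"):
        denom = k * beta * np.sum(w * np.expm1((x / beta) ** alpha))
    if not np.isfinite(denom) or denom <= 0:
        raise FloatingPointError("lambda profile denominator overflowed or is nonpositive")
    return m / denom


@dataclass
class MLEFit:
    """Maximum-likelihood fit: estimates, covariance, and diagnostics.

    ``cov`` is the inverse observed information in (alpha, beta, lam) order.
    ``boundary`` marks Weibull-ridge escapes (beta-hat at the large-beta
    identifiability boundary); such fits maximize the likelihood but their
    (beta, lam) components are not meaningfully identified.
    """

    params_hat: MWDParams
    loglik: float
    cov: np.ndarray
    converged: bool
    n_iter: int
    boundary: bool = False
    cov_warning: str = ""

    @property
    def se(self) -> np.ndarray:
        d = np.diag(self.cov)
        return np.sqrt(np.where(d > 0, d, np.nan))

    def to_json(self) -> str:
        p = self.params_hat
        return json.dumps(
            {
                "alpha": p.alpha, "beta": p.beta, "lam": p.lam,
                "loglik": self.loglik, "cov": self.cov.tolist(),
                "converged": self.converged, "boundary": self.boundary,
                "n_iter": self.n_iter, "cov_warning": self.cov_warning,
            }
        )


def fit_mle(
    s: PFFCSample,
    init: MWDParams | None = None,
    n_starts: int = 1,
    rng: np.random.Generator | None = None,
) -> MLEFit:
    """Maximize the PFFC log-likelihood over the positive octant.

    Strategy: Nelder-Mead over (log alpha, log beta) with lam profiled out
    in closed form, then a joint BFGS polish in log-parameters using the
    analytic score.  Additional random restarts (``n_starts > 1``) perturb
    the initial point; the best optimum wins.
    """
    x, w, n, m, k = _unpack(s)
    if m < 3:
        raise ValueError("need at least m=3 observations for a 3-parameter fit")
    if np.ptp(x) == 0:
        return MLEFit(
            params_hat=MWDParams(1.0, float(x[0]), 1.0), loglik=-np.inf,
            cov=np.full((3, 3), np.nan), converged=False, n_iter=0,
            cov_warning="degenerate data: all observations equal",
        )

    # Search box in (log alpha, log beta).  The likelihood can rise gently
    # toward the beta -> inf Weibull boundary while a better interior
    # maximum exists at moderate beta; the quadratic penalty keeps the
    # simplex from sliding off the ridge.  Genuine boundary cases end up on
    # the box edge and are flagged after the unconstrained polish.
    lo = np.array([-8.0, np.log(np.min(x)) - 4.0])
    hi = np.array([8.0, np.log(np.max(x)) + 4.0])

    def nll_profiled(u):
        uc = np.clip(u, lo, hi)
        pen = 1e3 * np.sum((u - uc) ** 2)
        a, b = np.exp(uc)
        with np.errstate(all="ignore"):
            denom = k * b * np.sum(w * np.expm1((x / b) ** a))
            if not np.isfinite(denom) or denom <= 0:
                return 1e12
            lam = m / denom
            v = _loglik_arr((a, b, lam), x, w, n, m, k)
        return -v + pen if np.isfinite(v) else 1e12

    def nll_joint(u):
        t = np.exp(u)
        with np.errstate(all="ignore"):
            v = _loglik_arr(t, x, w, n, m, k)
            if not np.isfinite(v):
                return 1e12, np.zeros(3)
            g = _score_arr(t, x, w, n, m, k) * t  # chain rule to log-params
        g = np.where(np.isfinite(g), g, 0.0)
        return -v, -g

    if init is not None:
        starts = [np.log([init.alpha, init.beta])]
    else:
        # spread over the beta ridge: around the data median and beyond max
        starts = [
            np.array([0.0, np.log(np.median(x))]),
            np.array([0.0, np.log(np.max(x))]),
            np.array([np.log(0.5), np.log(2.0 * np.max(x))]),
        ]
    if n_starts > 1:
        rng = rng or np.random.default_rng(0)
        starts += [starts[0] + rng.normal(0.0, 0.5, size=2) for _ in range(n_starts - 1)]

    # Nelder-Mead each start on the profiled surface, then a single joint
    # BFGS polish of the best candidate.
    best2 = None
    n_iter = 0
    for u0 in starts:
        r = minimize(
            nll_profiled, u0, method="Nelder-Mead",
            options=dict(xatol=1e-6, fatol=1e-9, maxiter=2000),
        )
        n_iter += r.nit
        if best2 is None or r.fun < best2.fun:
            best2 = r

    best = None
    if best2 is not None and best2.fun < 1e11:
        a, b = np.exp(np.clip(best2.x, lo, hi))
        with np.errstate(all="ignore"):
            lam = m / (k * b * np.sum(w * np.expm1((x / b) ** a)))
        if np.isfinite(lam) and lam > 0:
            u3 = np.log([a, b, lam])
            nl0 = nll_joint(u3)[0]
            r2 = minimize(nll_joint, u3, jac=True, method="BFGS",
                          options=dict(gtol=1e-9, maxiter=300))
            n_iter += r2.nit
            if r2.fun <= nl0:
                best = (r2.fun, np.exp(r2.x))
            else:
                best = (nl0, np.array([a, b, lam]))

    if best is None:
        return MLEFit(
            params_hat=MWDParams(1.0, float(np.median(x)), 1.0), loglik=-np.inf,
            cov=np.full((3, 3), np.nan), converged=False, n_iter=n_iter,
            cov_warning="all starts failed",
        )

    theta = best[1]
    p_hat = MWDParams.from_array(theta)
    ll = loglik(p_hat, s)
    with np.errstate(over="ignore"):
        g_scaled = _score_arr(theta, x, w, n, m, k) * theta
    grad_ok = np.all(np.isfinite(g_scaled)) and np.max(np.abs(g_scaled)) < 1e-3 * max(1.0, m)
    boundary = bool(
        theta[1] > _BOUNDARY_FACTOR * np.max(x)
        or theta[1] < np.min(x) / _BOUNDARY_FACTOR
    )

    info = observed_info(p_hat, s)
    cov_warning = ""
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        cov_warning = "observed information singular; pseudo-inverse used"
    return MLEFit(
        params_hat=p_hat, loglik=ll, cov=cov, converged=bool(grad_ok),
        n_iter=n_iter, boundary=boundary, cov_warning=cov_warning,
    )


def observed_info(p: MWDParams, s: PFFCSample, method: str = "fd", rel_step: float = 1e-5) -> np.ndarray:
    """Observed Fisher information: minus the Hessian of the log-likelihood.

    ``method='fd'`` differentiates the analytic score centrally (symmetrized);
    ``method='cs'`` uses complex-step derivatives of the score, exact to
    machine precision.
    """
    x, w, n, m, k = _unpack(s)
    theta = p.as_array()
    H = np.zeros((3, 3))
    if method == "cs":
        h = 1e-200
        for j in range(3):
            tj = theta.astype(complex)
            tj[j] += 1j * h
            H[:, j] = np.imag(_score_arr(tj, x, w, n, m, k)) / h
    elif method == "fd":
        with np.errstate(over="ignore"):
            for j in range(3):
                hj = rel_step * abs(theta[j])
                e = np.zeros(3)
                e[j] = hj
                H[:, j] = (
                    _score_arr(theta + e, x, w, n, m, k)
                    - _score_arr(theta - e, x, w, n, m, k)
                ) / (2.0 * hj)
    else:
        raise ValueError(f"unknown method {method!r}")
    H = 0.5 * (H + H.T)
    return -H


def wald_ci(fit: MLEFit, gamma: float = 0.05, truncate_at_zero: bool = False) -> dict:
    """(1-gamma) Wald intervals theta-hat +/- z_{gamma/2} * SE for each parameter.

    Intervals are not truncated at zero unless asked, matching common
    reporting of untruncated asymptotic intervals.
    """
    if not fit.converged:
        raise ValueError("cannot build Wald intervals from a non-converged fit")
    d = np.diag(fit.cov)
    if np.any(d < 0):
        raise ValueError("negative variance: observed information not positive definite")
    z = norm.ppf(1.0 - gamma / 2.0)
    out = {}
    for name, est, var in zip(("alpha", "beta", "lam"), fit.params_hat.as_array(), d):
        half = z * np.sqrt(var)
        lo, hi = est - half, est + half
        if truncate_at_zero:
            lo = max(lo, 0.0)
        out[name] = (float(lo), float(hi))
    return out


@dataclass(frozen=True)
class ReliabilityPoint:
    """S, h, r at a time point plus their delta-method variances."""

    t: float
    S: float
    h: float
    r: float
    var_S: float
    var_h: float
    var_r: float


def _reliability_grad(p: MWDParams, t: float, func) -> np.ndarray:
    theta = p.as_array()
    g = np.zeros(3)
    for j in range(3):
        hj = 1e-6 * abs(theta[j])
        tp, tm = theta.copy(), theta.copy()
        tp[j] += hj
        tm[j] -= hj
        g[j] = (func(t, MWDParams.from_array(tp)) - func(t, MWDParams.from_array(tm))) / (2 * hj)
    return g


def reliability_point(p: MWDParams, t: float, cov: np.ndarray | None = None) -> ReliabilityPoint:
    """Plug-in S(t), h(t), r(t) with gradient-sandwich variances (0 if no cov)."""
    if t <= 0:
        raise ValueError("t must be > 0")
    vals = {}
    vars_ = {}
    for name, func in (("S", sf), ("h", hrf), ("r", ihrf)):
        vals[name] = float(func(t, p))
        if cov is None:
            vars_[name] = 0.0
        else:
            g = _reliability_grad(p, t, func)
            vars_[name] = float(g @ cov @ g)
    return ReliabilityPoint(t=t, S=vals["S"], h=vals["h"], r=vals["r"],
                            var_S=vars_["S"], var_h=vars_["h"], var_r=vars_["r"])


def delta_ci(fit: MLEFit, t: float, gamma: float = 0.05) -> dict:
    """Delta-method (1-gamma) intervals for S(t), h(t), r(t) at the MLE."""
    rp = reliability_point(fit.params_hat, t, cov=fit.cov)
    z = norm.ppf(1.0 - gamma / 2.0)
    out = {}
    for name, est, var in (("S", rp.S, rp.var_S), ("h", rp.h, rp.var_h), ("r", rp.r, rp.var_r)):
        half = z * np.sqrt(max(var, 0.0))
        out[name] = (est - half, est + half)
    return out
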