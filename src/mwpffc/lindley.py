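"""Lindley-approximation Bayes estimates under gamma priors.

The posterior expectation of a smooth target g(alpha, beta, lam) is
approximated by Lindley's second-order expansion around the MLE,

    E[w] ~= w + sum_i w_i a_i + a4 + a5
            + (1/2) * sum_k [sum_ij l_ijk tau_ij] [sum_l w_l tau_kl],

with a_i = sum_j rho_j tau_ij, a4 = sum_{i<j} w_ij tau_ij,
a5 = (1/2) sum_i w_ii tau_ii, where rho is the log-prior gradient, tau the
inverse negative log-likelihood Hessian, and l_ijk the third-derivative
tensor, all evaluated at the MLE.

Loss functions: squared error (SELF; the posterior mean, w = g) and general
entropy (GELF; w = g**(-eps) followed by the outer power (.)**(-1/eps)).
At eps = -1 the GELF estimate coincides with SELF identically.  Independent
Gamma(a_i, b_i) priors on each parameter give
rho_i = (a_i - 1)/theta_i - b_i; all-zero hyperparameters reproduce the
Jeffreys-type prior 1/(alpha*beta*lam).

Lindley's approximation yields point estimates only; interval estimation
lives in :mod:`mwpffc.mcmc`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import PFFCSample
from .distribution import MWDParams, sf, hrf, ihrf
from .mle import MLEFit, fit_mle, observed_info

__all__ = ["GammaPriors", "LossSpec", "LindleyWorkspace", "lindley_workspace",
           "lindley_from_workspace", "lindley_estimate"]

_TARGETS = ("alpha", "beta", "lam", "S", "h", "r")


@dataclass(frozen=True)
class GammaPriors:
    """Independent gamma hyperparameters (a_i, b_i) for alpha, beta, lam."""

    a1: float = 0.0
    b1: float = 0.0
    a2: float = 0.0
    b2: float = 0.0
    a3: float = 0.0
    b3: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_tuple()):
            raise ValueError("hyperparameters must be nonnegative")

    def as_tuple(self):
        return (self.a1, self.b1, self.a2, self.b2, self.a3, self.b3)

    def log_prior_grad(self, theta: np.ndarray) -> np.ndarray:
        a = np.array([self.a1, self.a2, self.a3])
        b = np.array([self.b1, self.b2, self.b3])
        return (a - 1.0) / theta - b

    def log_prior(self, theta: np.ndarray) -> float:
        a = np.array([self.a1, self.a2, self.a3])
        b = np.array([self.b1, self.b2, self.b3])
        return float(np.sum((a - 1.0) * np.log(theta) - b * theta))


@dataclass(frozen=True)
class LossSpec:
    """SELF (posterior mean) or GELF with shape epsilon != 0."""

    kind: str = "SELF"
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("SELF", "GELF"):
            raise ValueError("loss kind must be SELF or GELF")
        if self.kind == "GELF" and (self.epsilon is None or self.epsilon == 0):
            raise ValueError("GELF requires a nonzero epsilon")


@dataclass
class LindleyWorkspace:
    """MLE-anchored ingredients shared by all targets: tau, rho, l_ijk."""

    fit: MLEFit
    theta: np.ndarray        # MLE triple
    tau: np.ndarray          # inverse negative Hessian, 3x3
    ell3: np.ndarray         # third-derivative tensor, 3x3x3
    rho: np.ndarray          # log-prior gradient at the MLE
    A: np.ndarray            # A_k = sum_ij ell3[i,j,k] * tau[i,j]


def _third_tensor(p: MWDParams, s: PFFCSample, rel_step: float = 1e-4) -> np.ndarray:
    """l_ijk by central differences (in k) of the complex-step Hessian."""
    theta = p.as_array()
    T = np.zeros((3, 3, 3))
    for k in range(3):
        h = rel_step * abs(theta[k])
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        Hp = -observed_info(MWDParams.from_array(tp), s, method="cs")
        Hm = -observed_info(MWDParams.from_array(tm), s, method="cs")
        T[:, :, k] = (Hp - Hm) / (2.0 * h)
    # enforce full symmetry (the analytic tensor is symmetric in all indices)
    Tsym = (T + T.transpose(0, 2, 1) + T.transpose(1, 0, 2)
            + T.transpose(1, 2, 0) + T.transpose(2, 0, 1) + T.transpose(2, 1, 0)) / 6.0
    return Tsym


def lindley_workspace(s: PFFCSample, priors: GammaPriors, fit: MLEFit | None = None) -> LindleyWorkspace:
    if fit is None:
        fit = fit_mle(s)
    theta = fit.params_hat.as_array()
    info = observed_info(fit.params_hat, s, method="cs")
    tau = np.linalg.inv(info)
    ell3 = _third_tensor(fit.params_hat, s)
    rho = priors.log_prior_grad(theta)
    A = np.einsum("ijk,ij->k", ell3, tau)
    return LindleyWorkspace(fit=fit, theta=theta, tau=tau, ell3=ell3, rho=rho, A=A)


def _target_fn(target: str, t: float | None):
    if target == "alpha":
        return lambda th: th[0]
    if target == "beta":
        return lambda th: th[1]
    if target == "lam":
        return lambda th: th[2]
    if target in ("S", "h", "r"):
        if t is None:
            raise ValueError(f"target {target!r} needs a time point t")
        func = {"S": sf, "h": hrf, "r": ihrf}[target]
        return lambda th: float(func(t, MWDParams.from_array(th)))
    raise ValueError(f"unknown target {target!r}; expected one of {_TARGETS}")


def _w_derivs(w, theta: np.ndarray, rel_step: float = 1e-5):
    """Value, gradient, and Hessian of w by central differences."""
    h = rel_step * np.abs(theta)
    w0 = w(theta)
    g = np.zeros(3)
    H = np.zeros((3, 3))
    for i in range(3):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        wp, wm = w(tp), w(tm)
        g[i] = (wp - wm) / (2 * h[i])
        H[i, i] = (wp - 2 * w0 + wm) / h[i] ** 2
    for i in range(3):
        for j in range(i + 1, 3):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[[i, j]] += h[[i, j]]
            tpm[i] += h[i]; tpm[j] -= h[j]
            tmp[i] -= h[i]; tmp[j] += h[j]
            tmm[[i, j]] -= h[[i, j]]
            H[i, j] = H[j, i] = (w(tpp) - w(tpm) - w(tmp) + w(tmm)) / (4 * h[i] * h[j])
    return w0, g, H


def _lindley_expectation(ws: LindleyWorkspace, w) -> float:
    w0, g, H = _w_derivs(w, ws.theta)
    tau = ws.tau
    a_vec = tau @ ws.rho                      # a_i = sum_j rho_j tau_ij
    a4 = np.sum(np.triu(H * tau, k=1))        # off-diagonal w_ij tau_ij once each
    a5 = 0.5 * np.sum(np.diag(H) * np.diag(tau))
    third = 0.5 * float(ws.A @ (tau @ g))
    return float(w0 + g @ a_vec + a4 + a5 + third)


def lindley_from_workspace(
    ws: LindleyWorkspace, target: str, t: float | None = None,
    loss: LossSpec = LossSpec("SELF"),
) -> float:
    g = _target_fn(target, t)
    if loss.kind == "SELF":
        return _lindley_expectation(ws, g)
    eps = loss.epsilon
    inner = _lindley_expectation(ws, lambda th: g(th) ** (-eps))
    if eps == -1.0:
        # the outer power is the identity; valid for any sign of the inner
        # expectation and coincides with SELF exactly
        return float(inner)
    if inner <= 0:
        raise FloatingPointError(
            f"GELF inner expectation {inner:.4g} <= 0: Lindley approximation broke down"
        )
    return float(inner ** (-1.0 / eps))


def lindley_estimate(
    s: PFFCSample,
    priors: GammaPriors,
    target: str,
    t: float | None = None,
    loss: LossSpec = LossSpec("SELF"),
    fit: MLEFit | None = None,
) -> float:
    """Lindley-approximation Bayes estimate of one target quantity.

    ``target`` is one of alpha/beta/lam/S/h/r (the reliability targets need
    the evaluation time ``t``).  The MLE is computed internally unless a fit
    is supplied.
    """
    ws = lindley_workspace(s, priors, fit=fit)
    return lindley_from_workspace(ws, target, t=t, loss=loss)
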