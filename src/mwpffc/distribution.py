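"""The modified Weibull distribution (MWD) kernel.

Density, distribution, survival, hazard and inverse-hazard functions, the
closed-form quantile, and complete-sample generation for the law with

    S(t) = exp{ lam * beta * (1 - exp[(t/beta)**alpha]) },   t >= 0,

where ``alpha, beta, lam > 0``.  ``beta`` carries the time units; ``alpha``
controls the hazard shape (increasing for ``alpha >= 1``, bathtub for
``alpha < 1``); ``lam*beta`` is the dimensionless exponent scale.  At
``lam = 1`` the law reduces to the exponential-power distribution
EPD(alpha, beta); as ``beta -> inf`` with ``lam*beta**(1-alpha)`` held fixed
it degenerates to an ordinary two-parameter Weibull, a boundary that matters
for small-sample estimation (see the methods note).

Everything is evaluated in log space where feasible: ``logpdf``/``logsf``
are the primitives and ``pdf = exp(logpdf)``, so large ``(t/beta)**alpha``
underflow to 0/-inf instead of overflowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MWDParams", "logpdf", "pdf", "cdf", "sf", "logsf", "hrf", "ihrf",
    "quantile", "rand_complete", "hrf_minimum",
]


@dataclass(frozen=True)
class MWDParams:
    """Parameter triple (alpha, beta, lam), all strictly positive.

    alpha : dimensionless shape (hazard shape driver)
    beta  : shape/scale hybrid in time units
    lam   : rate-like scale factor (1/time)
    """

    alpha: float
    beta: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.lam], dtype=float)

    @staticmethod
    def from_array(theta) -> "MWDParams":
        a, b, l = np.asarray(theta, dtype=float)
        return MWDParams(float(a), float(b), float(l))


def _check_x(x, allow_zero: bool = True) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo = 0.0
    bad = (x < lo) | ~np.isfinite(x) if allow_zero else (x <= lo) | ~np.isfinite(x)
    if np.any(bad):
        raise ValueError("x must be finite and %s 0" % (">=" if allow_zero else ">"))
    return x


def logsf(x, p: MWDParams):
    """log S(x) = lam*beta*(1 - exp[(x/beta)**alpha]) = -lam*beta*expm1(z)."""
    x = _check_x(x)
    with np.errstate(over="ignore"):
        z = (x / p.beta) ** p.alpha
        out = -p.lam * p.beta * np.expm1(z)
    return out


def sf(x, p: MWDParams):
    return np.exp(logsf(x, p))


def cdf(x, p: MWDParams):
    """F(x) = 1 - exp{lam*beta*(1 - exp[(x/beta)**alpha])}."""
    return -np.expm1(logsf(x, p))


def logpdf(x, p: MWDParams):
    """log f, with f(0) handled as the limit: 0 density for alpha>1, lam for
    alpha=1, and a +inf sentinel for alpha<1 (bathtub pole at the origin)."""
    x = _check_x(x)
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    zero = x == 0.0
    with np.errstate(over="ignore", divide="ignore"):
        xs = np.where(zero, 1.0, x)  # placeholder; overwritten below
        z = (xs / p.beta) ** p.alpha
        out = (
            np.log(p.lam * p.alpha)
            + (p.alpha - 1.0) * np.log(xs / p.beta)
            + z
            - p.lam * p.beta * np.expm1(z)
        )
    if np.any(zero):
        if p.alpha > 1.0:
            out[zero] = -np.inf
        elif p.alpha == 1.0:
            out[zero] = np.log(p.lam)
        else:
            out[zero] = np.inf  # documented sentinel, not an error
    return float(out[0]) if scalar else out


def pdf(x, p: MWDParams):
    with np.errstate(over="ignore"):
        return np.exp(logpdf(x, p))


def hrf(t, p: MWDParams):
    """Hazard h(t) = lam*alpha*(t/beta)**(alpha-1)*exp[(t/beta)**alpha], t>0."""
    t = _check_x(t, allow_zero=False)
    with np.errstate(over="ignore"):
        z = (t / p.beta) ** p.alpha
        return p.lam * p.alpha * (t / p.beta) ** (p.alpha - 1.0) * np.exp(z)


def ihrf(t, p: MWDParams):
    """Reversed (inverse) hazard r(t) = f(t)/F(t), t > 0."""
    t = _check_x(t, allow_zero=False)
    return pdf(t, p) / cdf(t, p)


def hrf_minimum(p: MWDParams) -> float:
    """Location of the hazard minimum for alpha < 1.

    Setting d log h / dt = 0 gives t* = beta*((1-alpha)/alpha)**(1/alpha);
    for alpha >= 1 the hazard is increasing everywhere and 0.0 is returned.
    """
    if p.alpha >= 1.0:
        return 0.0
    return p.beta * ((1.0 - p.alpha) / p.alpha) ** (1.0 / p.alpha)


def quantile(u, p: MWDParams):
    """Closed-form inverse CDF.

    x = beta * [ log(1 - log(1-u)/(lam*beta)) ]**(1/alpha), 0 <= u < 1.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u >= 1.0) | ~np.isfinite(u)):
        raise ValueError("u must lie in [0, 1)")
    inner = np.log1p(-np.log1p(-u) / (p.lam * p.beta))
    return p.beta * inner ** (1.0 / p.alpha)


def rand_complete(nobs: int, p: MWDParams, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. MWD draws by inverse-CDF sampling of uniforms."""
    if nobs < 1:
        raise ValueError("nobs must be >= 1")
    return quantile(rng.uniform(size=nobs), p)
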