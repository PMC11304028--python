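"""Progressive first-failure censoring schemes and sample generation.

A scheme places ``n`` groups of ``k`` units on test; at the i-th observed
first failure, ``R_i`` whole surviving groups are withdrawn, leaving ``m``
observed first-failure times.  Removing everything at the start, middle or
end gives the three standard layouts SC1, SC2 and SC3.

Generation follows the classic progressive type-II uniform construction
(Balakrishnan-Sandhu): draw ``W_i ~ U(0,1)``, set
``V_i = W_i**(1/(i + R_m + ... + R_{m-i+1}))`` and
``U_i = 1 - V_m*V_{m-1}*...*V_{m-i+1}``, which is a progressively censored
uniform sample; the first-failure times are then the inverse of the
transformed CDF ``1 - (1-F)**k`` applied to ``U_i``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distribution import MWDParams, quantile

__all__ = [
    "CensoringScheme", "PFFCSample", "make_scheme", "sample_pffc",
    "write_sample", "read_sample",
]


@dataclass(frozen=True)
class CensoringScheme:
    """(n, m, k, R): group count, observed failures, group size, removals."""

    n: int
    m: int
    k: int
    R: tuple = field(default=())

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.n):
            raise ValueError(f"need 1 <= m <= n, got m={self.m}, n={self.n}")
        if self.k < 1:
            raise ValueError("group size k must be >= 1")
        R = tuple(int(r) for r in self.R)
        object.__setattr__(self, "R", R)
        if len(R) != self.m:
            raise ValueError(f"R must have length m={self.m}, got {len(R)}")
        if any(r < 0 for r in R):
            raise ValueError("removal counts must be nonnegative")
        if sum(R) != self.n - self.m:
            raise ValueError(
                f"sum(R)={sum(R)} but n-m={self.n - self.m}; scheme invariant violated"
            )

    @property
    def R_array(self) -> np.ndarray:
        return np.asarray(self.R, dtype=int)


@dataclass(frozen=True)
class PFFCSample:
    """Ordered first-failure times together with their censoring scheme."""

    scheme: CensoringScheme
    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (self.scheme.m,):
            raise ValueError(f"expected {self.scheme.m} observations, got {x.shape}")
        if np.any(x < 0) or np.any(np.diff(x) < 0):
            raise ValueError("times must be nonnegative and nondecreasing")
        object.__setattr__(self, "x", x)


def make_scheme(kind: str, n: int, m: int, k: int) -> CensoringScheme:
    """Build one of the standard removal layouts SC1/SC2/SC3.

    SC1 removes all n-m groups at the first failure, SC3 at the last; SC2
    splits them across the middle (positions m/2 and m/2+1 for even m, the
    single middle position for odd m).  An odd n-m with even m cannot be
    split evenly; the floor/ceil split is used with a warning.
    """
    kind = kind.upper()
    if kind not in {"SC1", "SC2", "SC3"}:
        raise ValueError(f"unknown scheme kind {kind!r}")
    R = [0] * m
    rem = n - m
    if kind == "SC1":
        R[0] = rem
    elif kind == "SC3":
        R[-1] = rem
    else:
        if m % 2 == 1:
            R[(m + 1) // 2 - 1] = rem
        else:
            if rem % 2 == 1:
                warnings.warn(
                    f"SC2 with even m={m} and odd n-m={rem}: using floor/ceil split",
                    stacklevel=2,
                )
            lo = rem // 2
            R[m // 2 - 1] = lo
            R[m // 2] = rem - lo
    return CensoringScheme(n=n, m=m, k=k, R=tuple(R))


def _progressive_uniform(scheme: CensoringScheme, rng: np.random.Generator) -> np.ndarray:
    """Progressively type-II censored U(0,1) sample U_1 < ... < U_m."""
    R = scheme.R_array
    m = scheme.m
    W = rng.uniform(size=m)
    # exponent for V_i: i + R_m + ... + R_{m-i+1}  (i plus the last i removals)
    ex = np.arange(1, m + 1) + np.cumsum(R[::-1])
    V = W ** (1.0 / ex)
    # U_i = 1 - V_m V_{m-1} ... V_{m-i+1}
    U = 1.0 - np.cumprod(V[::-1])
    return U


def sample_pffc(p: MWDParams, scheme: CensoringScheme, rng: np.random.Generator) -> PFFCSample:
    """Draw one PFFC sample from the MWD.

    The first-failure times of groups of size k follow the transformed CDF
    ``F*(x) = 1 - (1-F(x))**k``, so ``X_i = F^{-1}(1 - (1-U_i)**(1/k))`` for
    the progressive uniform sample ``U_i``.
    """
    U = _progressive_uniform(scheme, rng)
    u_star = -np.expm1(np.log1p(-U) / scheme.k)  # 1 - (1-U)^(1/k), stably
    x = quantile(u_star, p)
    return PFFCSample(scheme=scheme, x=x)


def write_sample(s: PFFCSample, path) -> None:
    """Serialize to CSV (index, x, R) with a JSON header line for (n, m, k)."""
    path = Path(path)
    header = json.dumps({"n": s.scheme.n, "m": s.scheme.m, "k": s.scheme.k})
    lines = ["# " + header, "index,x,R"]
    for i, (xi, ri) in enumerate(zip(s.x, s.scheme.R), start=1):
        lines.append(f"{i},{float(xi)!r},{ri}")
    path.write_text("\n".join(lines) + "\n")


def read_sample(path) -> PFFCSample:
    """Read a sample written by :func:`write_sample`, revalidating the scheme."""
    lines = Path(path).read_text().strip().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError("missing JSON header line")
    meta = json.loads(lines[0][1:].strip())
    rows = [ln.split(",") for ln in lines[2:] if ln.strip()]
    x = np.array([float(r[1]) for r in rows])
    R = tuple(int(r[2]) for r in rows)
    scheme = CensoringScheme(n=meta["n"], m=meta["m"], k=meta["k"], R=R)
    return PFFCSample(scheme=scheme, x=x)
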