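"""Circular-statistics primitives.

Everything downstream (reliability mapping, integration models, the
behavioural pipeline) is built on the functions here: the von Mises density
and sampler, resultant-vector summaries, the Rayleigh test of circular
uniformity, and two estimators of the von Mises concentration parameter
kappa (a fast piecewise approximation and a maximum-likelihood oracle).

All angles are radians internally; conversion to/from degrees happens at the
I/O boundary (see :mod:`cueint.io_cli`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "VonMisesParams",
    "ResultantSummary",
    "wrap_angle",
    "von_mises_pdf",
    "sample_von_mises",
    "mean_resultant",
    "rayleigh_test",
    "kappa_fisher",
    "kappa_ml_oracle",
]

TWO_PI = 2.0 * math.pi


def wrap_angle(x):
    """Wrap angle(s) to the interval (-pi, pi].

    Accepts a scalar or array; returns the same shape. The result is
    congruent to ``x`` modulo 2*pi.

    Raises
    ------
    ValueError
        If any input is non-finite.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("angle must be finite")
    wrapped = arr - TWO_PI * np.floor((arr + math.pi) / TWO_PI)
    # floor maps the upper boundary pi to -pi; put it back on (-pi, pi]
    wrapped = np.where(wrapped <= -math.pi, math.pi, wrapped)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class VonMisesParams:
    """Mean direction and concentration of a von Mises distribution.

    ``mu`` is wrapped to (-pi, pi] on construction; ``kappa`` must be >= 0
    (kappa = 0 is the circular-uniform limit).
    """

    mu: float
    kappa: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.kappa) and self.kappa >= 0.0):
            raise ValueError(f"kappa must be finite and >= 0, got {self.kappa}")
        object.__setattr__(self, "mu", wrap_angle(self.mu))


def von_mises_pdf(x, p: VonMisesParams):
    """von Mises probability density exp(k*cos(x-mu)) / (2*pi*I0(k)).

    Evaluated with exponentially scaled Bessel terms so large kappa does not
    overflow. ``x`` may be a scalar or array (radians).
    """
    if p.kappa < 0:
        raise ValueError("kappa must be >= 0")
    x = np.asarray(x, dtype=float)
    # exp(k cos d) / I0(k) == exp(k (cos d - 1)) / i0e(k)
    dens = np.exp(p.kappa * (np.cos(x - p.mu) - 1.0)) / (TWO_PI * special.i0e(p.kappa))
    if dens.ndim == 0:
        return float(dens)
    return dens


def sample_von_mises(p: VonMisesParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` angles from a von Mises distribution, wrapped to (-pi, pi].

    Uses the generator's rejection sampler (Best & Fisher scheme);
    reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if p.kappa < 0:
        raise ValueError("kappa must be >= 0")
    if p.kappa == 0.0:
        draws = rng.uniform(-math.pi, math.pi, size=n)
    else:
        draws = rng.vonmises(p.mu, p.kappa, size=n)
    return wrap_angle(draws)


@dataclass(frozen=True)
class ResultantSummary:
    """Resultant-vector summary of a sample of angles.

    ``R`` is the mean vector length in [0, 1]; ``circ_sd`` is the circular
    standard deviation sqrt(-2 ln R), set to +inf (undefined) when R == 0.
    """

    mean_angle: float
    R: float
    n: int
    circ_sd: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.R <= 1.0 + 1e-12:
            raise ValueError(f"R out of range: {self.R}")
        object.__setattr__(self, "R", min(self.R, 1.0))
        sd = math.inf if self.R == 0.0 else math.sqrt(max(-2.0 * math.log(self.R), 0.0))
        object.__setattr__(self, "circ_sd", sd)


def mean_resultant(angles) -> ResultantSummary:
    """Mean resultant vector of a sample of angles (radians)."""
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("no data: at least one angle required")
    c = float(np.mean(np.cos(a)))
    s = float(np.mean(np.sin(a)))
    R = min(math.hypot(c, s), 1.0)
    mean_angle = wrap_angle(math.atan2(s, c)) if R > 0 else 0.0
    return ResultantSummary(mean_angle=mean_angle, R=R, n=int(a.size))


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(Z, p)`` with Z = n * R**2 and the p-value from the standard
    series approximation

        p = exp(-Z) * [1 + (2Z - Z^2)/(4n)
                         - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    clipped into (0, 1]. Requires n >= 2.
    """
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    n = a.size
    if n < 2:
        raise ValueError("Rayleigh test requires at least 2 angles")
    summary = mean_resultant(a)
    Z = n * summary.R**2
    p = math.exp(-Z) * (
        1.0
        + (2.0 * Z - Z**2) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n**2)
    )
    # the series misbehaves for Z large relative to n; clip into (0, 1]
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return float(Z), float(p)


def kappa_fisher(R: float, literal_product: bool = False) -> float:
    """Piecewise approximation of the von Mises concentration from R.

    Branches::

        R < 0.53   -> 2R + R^3 + (5/6) R^5
        R >= 0.85  -> 1 / (2(1-R) - (1-R)^2 - (1-R)^3)
        otherwise  -> -0.4 + 1.39 R + 0.43 / (1 - R)

    ``literal_product`` switches the middle branch's last term to the
    (nonsensical but sometimes-typeset) product form 0.43 * (1 - R); kept
    only for auditability, never used by default.
    """
    if not 0.0 <= R < 1.0:
        raise ValueError(f"R must lie in [0, 1), got {R}")
    if R < 0.53:
        return 2.0 * R + R**3 + (5.0 / 6.0) * R**5
    if R >= 0.85:
        u = 1.0 - R
        return 1.0 / (2.0 * u - u**2 - u**3)
    if literal_product:
        return -0.4 + 1.39 * R + 0.43 * (1.0 - R)
    return -0.4 + 1.39 * R + 0.43 / (1.0 - R)


def _bessel_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), computed with scaled Bessel functions."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_ml_oracle(R: float, tol: float = 1e-10) -> float:
    """Maximum-likelihood kappa: numerically invert A(kappa) = I1/I0 = R.

    Bracketed root finding to ``tol``; independent of :func:`kappa_fisher`
    and used as its test oracle.
    """
    if not 0.0 <= R < 1.0:
        raise ValueError(f"R must lie in [0, 1), got {R}")
    if R == 0.0:
        return 0.0
    hi = 2.0
    while _bessel_ratio(hi) < R:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - R this close to 1 is rejected above
            break
    return float(optimize.brentq(lambda k: _bessel_ratio(k) - R, 0.0, hi, xtol=tol))
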