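"""Shared fixtures and independent numeric oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest


def bessel_i0_series(x: float, terms: int = 60) -> float:
    """Modified Bessel I0 by direct series: sum (x/2)^(2m) / (m!)^2.

    Independent of scipy; oracle for density normalisation.
    """
    total, term = 1.0, 1.0
    for m in range(1, terms):
        term *= (x / 2.0) ** 2 / m**2
        total += term
    return total


def bessel_i1_series(x: float, terms: int = 60) -> float:
    """Modified Bessel I1 by direct series."""
    total = 0.0
    for m in range(terms):
        total += (x / 2.0) ** (2 * m + 1) / (math.factorial(m) * math.factorial(m + 1))
    return total


def polar_vector_sum_angle(thetas, weights) -> float:
    """Angle of the sum of polar vectors (theta, w): brute-force oracle."""
    z = sum(w * complex(math.cos(t), math.sin(t)) for t, w in zip(thetas, weights))
    return math.atan2(z.imag, z.real)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
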