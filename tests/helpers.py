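"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the chi-squared tail
is computed from a hand-rolled regularised incomplete gamma (series +
continued fraction), and linear-ODE trajectories come from the matrix
exponential, not from the package's integrator.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm

_EPS = 1e-16
_ITMAX = 500


def _gamma_series_p(a: float, x: float) -> float:
    """Regularised lower incomplete gamma P(a, x) by power series."""
    if x <= 0:
        return 0.0
    ap = a
    total = term = 1.0 / a
    for _ in range(_ITMAX):
        ap += 1.0
        term *= x / ap
        total += term
        if abs(term) < abs(total) * _EPS:
            break
    return total * math.exp(-x + a * math.log(x) - math.lgamma(a))


def _gamma_cf_q(a: float, x: float) -> float:
    """Regularised upper incomplete gamma Q(a, x) by continued fraction."""
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, _ITMAX + 1):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _EPS:
            break
    return math.exp(-x + a * math.log(x) - math.lgamma(a)) * h


def chi2_tail_oracle(x: float, k: int) -> float:
    """Pr(chi^2_k > x) via the regularised incomplete gamma Q(k/2, x/2)."""
    a, xs = k / 2.0, x / 2.0
    if xs < 0:
        return 1.0
    if xs < a + 1.0:
        return 1.0 - _gamma_series_p(a, xs)
    return _gamma_cf_q(a, xs)


def chi2_tail_even_k(x: float, k: int) -> float:
    """Closed form for even k: exp(-x/2) * sum_{j<k/2} (x/2)^j / j!."""
    assert k % 2 == 0
    half = x / 2.0
    total = term = 1.0
    for j in range(1, k // 2):
        term *= half / j
        total += term
    return math.exp(-half) * total


def affine_ode_solution(A: np.ndarray, b: np.ndarray, y0: np.ndarray, t: float) -> np.ndarray:
    """Exact solution of y' = A y + b at time t (A invertible)."""
    Ainv_b = np.linalg.solve(A, b)
    return expm(A * t) @ (y0 + Ainv_b) - Ainv_b
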