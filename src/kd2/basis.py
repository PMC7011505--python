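"""Discrete Krawtchouk polynomial machinery.

The Krawtchouk polynomials ``K_n(x; p, N)`` are orthogonal on the integer
grid ``{0, ..., N}`` with respect to the binomial weight
``w(x; p, N) = C(N, x) p^x (1 - p)^(N - x)``, with squared norms
``rho(n; p, N)``.  The weighted polynomials
``Kbar_n = K_n * sqrt(w / rho)`` are orthonormal, and their separable 2D
products give a localized moment basis: the envelope
``W_c(x, y) = sqrt(w(x) w(y))`` peaks at the centre of an S-by-S window
and decays rapidly, which is what confines each descriptor to the
neighbourhood of a point of interest.

Only the centred family (``p = 0.5``) up to order 3 is used by the
descriptor pipeline; off-centre regions are handled by translating the
weight, not by changing ``p``.  All binomial quantities are evaluated in
log space so that windows of a few hundred pixels do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .errors import ConfigurationError

#: Highest polynomial/moment order used anywhere in the pipeline.  The
#: descriptor keeps the six order-<=3 components; raising this constant is
#: the single switch needed to extend the basis.
ORDER_MAX = 3

#: Basis parameter of the centred family.
P_CENTER = 0.5

#: Smallest window for which third-order moments are meaningful.
MIN_WINDOW = 8


def binomial_weight(x, p: float, N: int):
    """Binomial probability mass ``w(x; p, N) = C(N, x) p^x (1-p)^(N-x)``.

    Parameters
    ----------
    x : int or array_like of int
        Evaluation point(s), each in ``0..N``.
    p : float
        Success probability, in the open interval (0, 1).
    N : int
        Grid order (the window holds ``N + 1`` samples).

    Returns
    -------
    float or ndarray
        The weight(s); computed via log-gamma so that e.g. ``N = 149``
        (a 150-pixel window) stays well inside double range.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    xa = np.asarray(x, dtype=np.float64)
    if np.any((xa < 0) | (xa > N)) or np.any(xa != np.floor(xa)):
        raise ValueError(f"x must be an integer in 0..{N}")
    logw = (
        gammaln(N + 1.0)
        - gammaln(xa + 1.0)
        - gammaln(N - xa + 1.0)
        + xa * np.log(p)
        + (N - xa) * np.log1p(-p)
    )
    w = np.exp(logw)
    return float(w) if np.isscalar(x) or np.ndim(x) == 0 else w


def krawtchouk_norm(n: int, p: float, N: int) -> float:
    """Squared norm ``rho(n; p, N)`` of the Krawtchouk polynomial ``K_n``.

    ``rho(n; p, N) = (-1)^n ((1-p)/p)^n n! / (-N)_n`` with the rising
    factorial ``(-N)_n = (-N)(-N+1)...(-N+n-1)``.  At ``p = 0.5`` this
    reduces to the closed form ``n! (N-n)! / N!``.
    """
    if n < 0 or n > N:
        raise ValueError(f"order n must satisfy 0 <= n <= N, got n={n}, N={N}")
    poch = 1.0
    fact = 1.0
    for k in range(n):
        poch *= -N + k
        fact *= k + 1
    return (-1.0) ** n * ((1.0 - p) / p) ** n * fact / poch


def krawtchouk_coeffs(n: int, p: float, N: int) -> np.ndarray:
    """Monomial coefficients of ``K_n(x; p, N)``.

    Returns ``a`` (length ``n + 1``, ascending powers) such that
    ``K_n(x) = sum_i a[i] x^i``.  The polynomial is the terminating
    hypergeometric sum ``sum_s (-n)_s (-x)_s / ((-N)_s s!) p^(-s)``;
    each falling factor ``(-x)_s`` is expanded by iterated polynomial
    multiplication.
    """
    if n < 0 or n > ORDER_MAX:
        raise ValueError(f"order n must be in 0..{ORDER_MAX}, got {n}")
    if n > N:
        raise ValueError(f"order n={n} exceeds grid order N={N}")
    coef = np.zeros(n + 1)
    coef[0] = 1.0
    poch_n = 1.0
    poch_N = 1.0
    fact = 1.0
    falling = np.array([1.0])  # expansion of (-x)_s, ascending powers
    for s in range(1, n + 1):
        poch_n *= -n + (s - 1)
        poch_N *= -N + (s - 1)
        fact *= s
        falling = np.polynomial.polynomial.polymul(falling, [s - 1.0, -1.0])
        coef[: s + 1] += (poch_n / (poch_N * fact)) * p ** (-s) * falling
    return coef


def krawtchouk_eval(n: int, x, p: float, N: int):
    """Evaluate ``K_n(x; p, N)`` from its monomial expansion."""
    return np.polynomial.polynomial.polyval(
        np.asarray(x, dtype=np.float64), krawtchouk_coeffs(n, p, N)
    )


def weighted_krawtchouk_eval(n: int, x, p: float, N: int):
    """Evaluate the orthonormal ``Kbar_n(x) = K_n(x) sqrt(w(x) / rho(n))``."""
    xa = np.asarray(x)
    return krawtchouk_eval(n, xa, p, N) * np.sqrt(
        binomial_weight(xa, p, N) / krawtchouk_norm(n, p, N)
    )


def central_weight(S: int) -> np.ndarray:
    """2D central weight ``W_c(x, y) = sqrt(w(x; 0.5, S-1) w(y; 0.5, S-1))``.

    The square root makes the descriptor sum over the weighted auxiliary
    image coincide with the weighted Krawtchouk moment
    ``sum Kbar_n(x) Kbar_m(y) f(x, y)``; consequently
    ``sum_{x,y} W_c^2 = 1`` and the envelope is symmetric about the
    window centre.
    """
    if S < MIN_WINDOW:
        raise ConfigurationError(f"window size S must be >= {MIN_WINDOW}, got {S}")
    sw = np.sqrt(binomial_weight(np.arange(S), P_CENTER, S - 1))
    return np.outer(sw, sw)


@dataclass(frozen=True)
class BasisConstants:
    """Precomputed constants for one window size ``S`` (pure function of S).

    Attributes
    ----------
    S : int
        Window size in pixels.
    p : float
        Basis parameter (always 0.5: centred family).
    rho : ndarray, shape (4,)
        Squared norms ``rho(n; 0.5, S-1)`` for n = 0..3.
    coeffs : tuple of ndarray
        ``coeffs[n]`` holds the ``n + 1`` monomial coefficients of ``K_n``.
    coeff_matrix : ndarray, shape (4, 4)
        ``coeff_matrix[n, i] = a_{i,n}`` (zero above the diagonal);
        convenient for matrix-form moment assembly.
    Wc : ndarray, shape (S, S)
        Central 2D weight ``W_c``.
    """

    S: int
    p: float
    rho: np.ndarray
    coeffs: tuple
    coeff_matrix: np.ndarray = field(repr=False)
    Wc: np.ndarray = field(repr=False)


@lru_cache(maxsize=32)
def prep_step(S: int) -> BasisConstants:
    """Bundle every constant the descriptor needs for window size ``S``.

    Deterministic and cached: repeated calls with the same ``S`` return
    the identical (read-only) object.
    """
    if S < MIN_WINDOW:
        raise ConfigurationError(
            f"window size S must be >= {MIN_WINDOW} for order-3 moments, got {S}"
        )
    N = S - 1
    rho = np.array([krawtchouk_norm(n, P_CENTER, N) for n in range(ORDER_MAX + 1)])
    coeffs = tuple(krawtchouk_coeffs(n, P_CENTER, N) for n in range(ORDER_MAX + 1))
    A = np.zeros((ORDER_MAX + 1, ORDER_MAX + 1))
    for n, c in enumerate(coeffs):
        A[n, : n + 1] = c
    Wc = central_weight(S)
    for arr in (rho, A, Wc):
        arr.setflags(write=False)
    for c in coeffs:
        c.setflags(write=False)
    return BasisConstants(S=S, p=P_CENTER, rho=rho, coeffs=coeffs, coeff_matrix=A, Wc=Wc)
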