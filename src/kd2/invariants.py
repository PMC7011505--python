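"""Geometric moments and translation/rotation/scale-invariant moments.

Given a weighted auxiliary image ``g`` on an S-by-S grid, this module
computes its raw and central geometric moments, the principal-axis angle,
and the normalized moments ``lambda_ij``: monomial moments evaluated in a
coordinate frame that has been translated to the centre of mass, rotated
by the principal angle and rescaled so that the total mass equals a fixed
reference ``beta``.  By construction ``lambda_ij`` is unchanged when the
underlying pattern is translated, rotated or (approximately, because the
weight envelope is fixed) scaled.

The normalized frame is

    u = gamma * [ (x - xc) cos(theta) + (y - yc) sin(theta) ] + c
    v = gamma * [ -(x - xc) sin(theta) + (y - yc) cos(theta) ] + c

with ``c = (S - 1) / 2``, ``gamma = sqrt(beta / M00)`` and

    lambda_ij = (beta / M00) * sum_{x,y} g(x, y) u^i v^j .

Pinning the transformed mass and centroid to ``beta`` and the grid centre
makes ``lambda_00 = beta`` and ``lambda_10 = lambda_01 = beta * c``
constants, which is precisely why the four lowest-order descriptors built
from them are discarded downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .basis import ORDER_MAX
from .errors import DegenerateRegionError

#: Relative mass threshold below which a region counts as blank.
DEGENERACY_EPS = 1e-12

#: Relative tolerance for third-moment sign tests and ambiguity checks.
_ANGLE_TOL = 1e-9


@dataclass
class MomentSummary:
    """Raw and central moments of an auxiliary image, plus its orientation."""

    m00: float
    xc: float
    yc: float
    mu20: float
    mu02: float
    mu11: float
    mu30: float
    mu03: float
    mu21: float
    mu12: float
    S: int
    theta: float | None = None
    ambiguous: bool = False


@dataclass
class InvariantSet:
    """Normalized moments ``lambda_ij`` (i, j = 0..3) with their scaling."""

    lam: np.ndarray  # (4, 4)
    beta: float
    gamma: float


def geometric_moments(g: np.ndarray, max_order: int = ORDER_MAX) -> dict:
    """Raw moments ``M_ij = sum_{x,y} x^i y^j g(x, y)`` for ``i + j <= max_order``.

    ``x`` runs over rows, ``y`` over columns.  Separable accumulation;
    agrees with the brute-force double loop to rounding error.
    """
    g = np.asarray(g, dtype=np.float64)
    nx, ny = g.shape
    xp = np.vander(np.arange(nx, dtype=np.float64), max_order + 1, increasing=True)
    yp = np.vander(np.arange(ny, dtype=np.float64), max_order + 1, increasing=True)
    full = xp.T @ g @ yp  # full[i, j] = M_ij
    return {
        (i, j): float(full[i, j])
        for i in range(max_order + 1)
        for j in range(max_order + 1)
        if i + j <= max_order
    }


def center_and_central_moments(g: np.ndarray) -> MomentSummary:
    """Centre of mass and central moments up to order 3 of ``g``.

    Raises :class:`DegenerateRegionError` when the region carries
    (numerically) no mass — a blank region of interest.
    """
    g = np.asarray(g, dtype=np.float64)
    S = g.shape[0]
    m00 = float(g.sum())
    if m00 <= DEGENERACY_EPS * g.size * 255.0:
        raise DegenerateRegionError(
            f"blank region of interest (mass {m00:.3e} below threshold)"
        )
    x = np.arange(g.shape[0], dtype=np.float64)[:, None]
    y = np.arange(g.shape[1], dtype=np.float64)[None, :]
    xc = float((x * g).sum()) / m00
    yc = float((y * g).sum()) / m00
    dx = x - xc
    dy = y - yc
    mu = {}
    for p, q in ((2, 0), (0, 2), (1, 1), (3, 0), (0, 3), (2, 1), (1, 2)):
        mu[(p, q)] = float((dx**p * dy**q * g).sum())
    return MomentSummary(
        m00=m00,
        xc=xc,
        yc=yc,
        mu20=mu[(2, 0)],
        mu02=mu[(0, 2)],
        mu11=mu[(1, 1)],
        mu30=mu[(3, 0)],
        mu03=mu[(0, 3)],
        mu21=mu[(2, 1)],
        mu12=mu[(1, 2)],
        S=S,
    )


def _rotated_second(ms: MomentSummary, theta: float) -> tuple[float, float]:
    c, s = math.cos(theta), math.sin(theta)
    m20 = ms.mu20 * c * c + 2.0 * ms.mu11 * c * s + ms.mu02 * s * s
    m02 = ms.mu20 * s * s - 2.0 * ms.mu11 * c * s + ms.mu02 * c * c
    return m20, m02


def _rotated_third(ms: MomentSummary, theta: float) -> tuple[float, float]:
    c, s = math.cos(theta), math.sin(theta)
    m30 = (
        ms.mu30 * c**3
        + 3.0 * ms.mu21 * c * c * s
        + 3.0 * ms.mu12 * c * s * s
        + ms.mu03 * s**3
    )
    m03 = (
        -ms.mu30 * s**3
        + 3.0 * ms.mu21 * s * s * c
        - 3.0 * ms.mu12 * s * c * c
        + ms.mu03 * c**3
    )
    return m30, m03


def _wrap_angle(t: float) -> float:
    """Map an angle to the interval (-pi, pi]."""
    t = (t + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if t == -math.pi else t


def principal_angle(ms: MomentSummary) -> MomentSummary:
    """Determine the unique principal-axis angle of the auxiliary image.

    The base angle ``theta0 = atan2(2 mu11, mu20 - mu02) / 2`` is defined
    only modulo pi/2; the returned representative (in (-pi, pi]) is the
    one for which, in the rotated frame, (a) ``mu'20 >= mu'02`` and
    (b) the dominant rotated third moment — ``mu'30`` when
    ``|mu'30| >= |mu'03|``, ``mu'03`` otherwise — is positive; when both
    third moments are below tolerance the smallest-magnitude candidate is
    returned.  Using the dominant third moment (rather than always
    ``mu'30``) keeps the convention stable for patterns that are mirror
    symmetric about their principal axis, where ``mu'30`` vanishes up to
    resampling noise while ``mu'03`` is well determined (or vice versa).
    A rotationally ambiguous region (``mu11 = 0`` and ``mu20 = mu02``)
    yields ``theta = 0`` with ``ambiguous`` set.

    Returns the summary with ``theta``/``ambiguous`` filled in.
    """
    tol2 = _ANGLE_TOL * ms.m00 * ms.S**2
    tol3 = _ANGLE_TOL * ms.m00 * ms.S**3
    if abs(ms.mu11) <= tol2 and abs(ms.mu20 - ms.mu02) <= tol2:
        ms.theta = 0.0
        ms.ambiguous = True
        return ms
    theta0 = 0.5 * math.atan2(2.0 * ms.mu11, ms.mu20 - ms.mu02)
    cands = [_wrap_angle(theta0 + k * math.pi / 2.0) for k in range(4)]
    eligible = [t for t in cands if _rotated_second(ms, t)[0] >= _rotated_second(ms, t)[1] - tol2]
    if not eligible:  # numerical guard; cannot happen analytically
        eligible = cands
    positive = []
    for t in eligible:
        m30, m03 = _rotated_third(ms, t)
        dominant = m30 if abs(m30) >= abs(m03) else m03
        if dominant > tol3:
            positive.append(t)
    pool = positive if positive else eligible
    ms.theta = min(pool, key=lambda t: (abs(t), -t))
    ms.ambiguous = False
    return ms


def geometric_invariants(
    g: np.ndarray, ms: MomentSummary, beta: float
) -> InvariantSet:
    """Normalized moments ``lambda_ij`` of the auxiliary image ``g``.

    ``beta`` is the reference mass every region is normalized to; it must
    be identical for index and query descriptors to be comparable.
    """
    if ms.theta is None:
        ms = principal_angle(ms)
    g = np.asarray(g, dtype=np.float64)
    S = g.shape[0]
    c = (S - 1) / 2.0
    gamma = math.sqrt(beta / ms.m00)
    ct, st = math.cos(ms.theta), math.sin(ms.theta)
    x = np.arange(g.shape[0], dtype=np.float64)[:, None]
    y = np.arange(g.shape[1], dtype=np.float64)[None, :]
    dx = x - ms.xc
    dy = y - ms.yc
    u = gamma * (dx * ct + dy * st) + c
    v = gamma * (-dx * st + dy * ct) + c
    up = np.stack([np.ones_like(u), u, u * u, u**3])
    vp = np.stack([np.ones_like(v), v, v * v, v**3])
    lam = (beta / ms.m00) * np.einsum("ixy,jxy->ij", up * g, vp)
    return InvariantSet(lam=lam, beta=float(beta), gamma=gamma)
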