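"""Assembly of the six-component local Krawtchouk descriptor.

For a point of interest at window coordinates ``(x_s, y_s)`` inside an
S-by-S crop ``f_s``, the pipeline is:

1. translate the central weight ``W_c`` so its peak sits on the point
   (:func:`shift_weight`);
2. form the auxiliary image ``f~ = f_s * W_s`` (:func:`auxiliary_image`),
   which suppresses content far from the point;
3. compute the normalized geometric moments ``lambda_ij`` of ``f~``
   (translation/rotation/scale invariant, see :mod:`kd2.invariants`);
4. combine them into weighted Krawtchouk moments

       Q_nm = [rho(n) rho(m)]^(-1/2)
              * sum_{i<=n} sum_{j<=m} a_{i,n} a_{j,m} lambda_ij

   for n, m = 0..3 and keep the six informative components

       V = [Q_20, Q_02, Q_12, Q_21, Q_30, Q_03].

``Q_00``, ``Q_01``, ``Q_10`` and ``Q_11`` are constants by construction
(the normalization pins mass, centroid and the mixed second moment) and
are therefore discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisConstants
from .errors import ConfigurationError
from .image_io import DensityImage
from .invariants import (
    InvariantSet,
    center_and_central_moments,
    geometric_invariants,
    principal_angle,
)

#: Component order of the descriptor vector.
COMPONENT_NAMES = ("q20", "q02", "q12", "q21", "q30", "q03")
_COMPONENT_INDEX = ((2, 0), (0, 2), (1, 2), (2, 1), (3, 0), (0, 3))


def default_beta(S: int) -> float:
    """Default reference mass ``beta = S^2 / 12``.

    The value of the reference mass is a free calibration constant: it
    sets the spatial spread of the normalized pattern inside the S-by-S
    grid (``S^2/12`` is the variance of a uniform spread over the window,
    which keeps typical patterns well inside it).  Any value works as
    long as index and query share it.
    """
    return S * S / 12.0


@dataclass
class Descriptor:
    """A six-component descriptor attached to an image and a point."""

    v: np.ndarray
    image_id: str = ""
    x_p: int = 0
    y_p: int = 0
    S: int = 0
    beta: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.v, dtype=np.float64)
        if v.shape != (6,):
            raise ConfigurationError(f"descriptor must have 6 components, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("descriptor contains non-finite components")
        self.v = v

    def as_row(self) -> dict:
        row = {"image_id": self.image_id, "x_p": self.x_p, "y_p": self.y_p}
        row.update(zip(COMPONENT_NAMES, self.v))
        return row


def shift_weight(Wc: np.ndarray, x_s: float, y_s: float) -> np.ndarray:
    """Translate the central weight so its peak sits at ``(x_s, y_s)``.

    ``W_s(x, y) = W_c(x*, y*)`` with ``x* = x - x_s + (S-1)/2`` and
    ``y* = y - y_s + (S-1)/2`` rounded to the nearest grid point (so the
    envelope's centre lands on the point of interest); positions falling
    outside the grid contribute zero, hence part of the envelope is
    truncated near window borders.
    """
    S = Wc.shape[0]
    if Wc.shape != (S, S):
        raise ConfigurationError(f"weight grid must be square, got {Wc.shape}")
    if not (0 <= x_s <= S - 1 and 0 <= y_s <= S - 1):
        raise ConfigurationError(
            f"point ({x_s}, {y_s}) outside the {S}x{S} window"
        )
    off = (S - 1) / 2.0
    ix = np.floor(np.arange(S) - x_s + off + 0.5).astype(np.int64)
    iy = np.floor(np.arange(S) - y_s + off + 0.5).astype(np.int64)
    mx = (ix >= 0) & (ix < S)
    my = (iy >= 0) & (iy < S)
    Ws = np.zeros_like(Wc)
    Ws[np.ix_(mx, my)] = Wc[np.ix_(ix[mx], iy[my])]
    return Ws


def auxiliary_image(f_s, W_s: np.ndarray) -> np.ndarray:
    """Pointwise product ``f~ = f_s * W_s`` localizing the window content."""
    px = f_s.pixels if isinstance(f_s, DensityImage) else np.asarray(f_s, dtype=np.float64)
    if px.shape != W_s.shape:
        raise ConfigurationError(
            f"image {px.shape} and weight {W_s.shape} shapes differ"
        )
    return px * W_s


def krawtchouk_moment_matrix(inv: InvariantSet, const: BasisConstants) -> np.ndarray:
    """Full 4-by-4 matrix of weighted Krawtchouk moments ``Q_nm``.

    ``Q = D A lambda A^T D`` with ``A[n, i] = a_{i,n}`` and
    ``D = diag(rho^(-1/2))``.  Exposed separately from :func:`comp_desc`
    so the constancy of the discarded low-order components can be
    observed directly.
    """
    A = const.coeff_matrix
    D = 1.0 / np.sqrt(const.rho)
    return (A @ inv.lam @ A.T) * np.outer(D, D)


def comp_desc(
    f_s,
    x_s: int,
    y_s: int,
    const: BasisConstants,
    beta: float | None = None,
    *,
    image_id: str = "",
    poi: tuple[int, int] | None = None,
) -> Descriptor:
    """Compute the descriptor of the point ``(x_s, y_s)`` in window ``f_s``.

    Parameters
    ----------
    f_s : DensityImage or ndarray
        S-by-S square crop containing the point of interest.
    x_s, y_s : int
        Point of interest in window coordinates (fractional values are
        rounded to the nearest pixel).
    const : BasisConstants
        Output of :func:`kd2.basis.prep_step` for the same ``S``.
    beta : float, optional
        Reference mass; defaults to ``S^2 / 12``.  Must match between
        index and query.
    image_id, poi : optional
        Provenance recorded on the returned descriptor; ``poi`` is the
        point in source-image coordinates (defaults to window coords).

    Raises
    ------
    DegenerateRegionError
        If the weighted window carries no mass (blank region); such
        points are unusable and must not be silently zeroed.
    """
    px = f_s.pixels if isinstance(f_s, DensityImage) else np.asarray(f_s, dtype=np.float64)
    S = const.S
    if px.shape != (S, S):
        raise ConfigurationError(
            f"window shape {px.shape} does not match basis constants S={S}"
        )
    if beta is None:
        beta = default_beta(S)
    x_s = int(round(x_s))
    y_s = int(round(y_s))
    Ws = shift_weight(const.Wc, x_s, y_s)
    g = auxiliary_image(px, Ws)
    ms = principal_angle(center_and_central_moments(g))
    inv = geometric_invariants(g, ms, beta)
    Q = krawtchouk_moment_matrix(inv, const)
    v = np.array([Q[n, m] for n, m in _COMPONENT_INDEX])
    if isinstance(f_s, DensityImage) and not image_id:
        image_id = f_s.image_id
    x_p, y_p = poi if poi is not None else (x_s, y_s)
    return Descriptor(
        v=v, image_id=image_id, x_p=int(x_p), y_p=int(y_p), S=S, beta=float(beta)
    )
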