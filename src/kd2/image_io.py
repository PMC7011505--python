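"""Reading gray-scale images and cropping square working windows.

Coordinate convention used throughout the package: ``x`` indexes rows and
``y`` indexes columns, both 0-based with the origin at the top-left pixel,
so an image is the density ``f(x, y)`` on ``{0..N-1} x {0..M-1}``.
Densities live on the 0..255 scale regardless of the source bit depth;
descriptors are mass-normalized downstream, so only the shared convention
matters, not the absolute scale.

Polarity is never changed here: queries and databases must agree on
bright-on-dark versus dark-on-bright content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError

#: Rec. 709 luminance weights for RGB-to-gray conversion.
_LUMA = np.array([0.2125, 0.7154, 0.0721])

MIN_DIM = 8


class PointOfInterest(NamedTuple):
    """Pixel location (row ``x``, column ``y``) a descriptor is attached to."""

    x: int
    y: int


@dataclass
class DensityImage:
    """A 2D grid of nonnegative pixel densities with an opaque label."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ConfigurationError(f"expected a 2D grid, got shape {px.shape}")
        if px.shape[0] < MIN_DIM or px.shape[1] < MIN_DIM:
            raise ConfigurationError(
                f"image must be at least {MIN_DIM}x{MIN_DIM}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ConfigurationError("image contains non-finite pixel values")
        if np.any(px < 0):
            raise ConfigurationError("image contains negative densities")
        self.pixels = px

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse channels (if any) to luminance and rescale to 0..255."""
    a = np.asarray(arr)
    if a.ndim == 3:
        if a.shape[2] == 4:  # drop alpha
            a = a[:, :, :3]
        if a.shape[2] == 3:
            a = a.astype(np.float64) @ _LUMA
        else:
            a = a[:, :, 0].astype(np.float64)
    if arr.dtype == np.uint16:
        return a.astype(np.float64) / 257.0  # 65535 -> 255
    return a.astype(np.float64)


def read_image(path) -> tuple[DensityImage, int]:
    """Read a raster image file as a density grid.

    Returns the :class:`DensityImage` and a default window size
    ``S = min(N, M)``; callers typically override ``S`` with the size of
    the patterns they search for.

    Raises
    ------
    OSError
        If the file is missing or cannot be decoded.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    px = np.clip(_to_gray(arr), 0.0, None)
    img = DensityImage(px, image_id=path.stem)
    return img, min(img.n_rows, img.n_cols)


def square_crop(
    f: DensityImage, poi: PointOfInterest, S: int
) -> tuple[DensityImage, int, int]:
    """Crop the S-by-S window containing ``poi``.

    The window is centred on the point of interest when possible; near a
    border it is clamped to lie fully inside the image (never padded), so
    the output is always exactly S-by-S and the point always lies inside
    it.  Returns the window together with the point's coordinates
    ``(x_s, y_s)`` relative to the window's top-left corner.
    """
    N, M = f.pixels.shape
    if S > min(N, M):
        raise ConfigurationError(
            f"window size {S} exceeds image dimensions {N}x{M}"
        )
    x, y = int(poi[0]), int(poi[1])
    if not (0 <= x < N and 0 <= y < M):
        raise ConfigurationError(f"point of interest {poi} outside image {N}x{M}")
    r0 = min(max(x - S // 2, 0), N - S)
    c0 = min(max(y - S // 2, 0), M - S)
    win = DensityImage(
        f.pixels[r0 : r0 + S, c0 : c0 + S].copy(), image_id=f.image_id
    )
    return win, x - r0, y - c0
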