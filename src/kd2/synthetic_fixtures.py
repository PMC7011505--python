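"""Synthetic retrieval benchmark: icons, transformed copies, noisy canvases.

The benchmark emulates a classic local-retrieval protocol: a small set of
distinct gray-scale icons is rotated through twelve angles (0, 30, ...,
330 degrees) and scaled by three factors (0.8, 0.9, 1.0), and every
(icon, angle, scale) combination is placed once, at a randomly assigned
slot, on a 9-by-9 grid of slot centres spread over four 600x600 canvases
(9 * 12 * 3 = 324 = 81 * 4 placements).  The untransformed icons, centred
in 150x150 frames, serve as queries.  Optionally the whole dataset —
canvases and query frames alike — is degraded with salt-and-pepper noise
before indexing to probe descriptor robustness.

Icons are procedurally drawn filled silhouettes (ellipse, triangle,
pac-man, teardrop, crescent, ...), bright on a black background, and are
required to be
*separable*: the descriptor distance between any two distinct icons must
exceed ten times the distance between an icon and its own 30-degree
rotated copy, otherwise generation retries with fresh shape jitter.
Everything is driven by a single seed and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.transform import rescale, rotate

from .basis import prep_step
from .descriptor import Descriptor, comp_desc, default_beta
from .errors import ConfigurationError, GenerationError
from .image_io import DensityImage, PointOfInterest
from .index_search import SearchResult, db_index, db_search

TRUTH_COLUMNS = ["canvas", "x", "y", "icon", "angle", "scale"]


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of the synthetic benchmark (defaults replicate the
    324-subimage / four-canvas protocol)."""

    n_icons: int = 9
    angles: tuple = tuple(range(0, 360, 30))
    scales: tuple = (0.8, 0.9, 1.0)
    canvas: int = 600
    slots: int = 81  # must be a square number (slot grid is square)
    n_canvases: int = 4
    icon_size: int = 60
    frame: int = 150
    seed: int = 0

    def __post_init__(self):
        side = int(round(self.slots**0.5))
        if side * side != self.slots:
            raise ConfigurationError(f"slots must be a square number, got {self.slots}")
        if self.slots * self.n_canvases < self.n_combos:
            raise ConfigurationError(
                f"{self.n_combos} combinations do not fit in "
                f"{self.slots * self.n_canvases} slots"
            )

    @property
    def n_combos(self) -> int:
        return self.n_icons * len(self.angles) * len(self.scales)

    @property
    def grid_side(self) -> int:
        return int(round(self.slots**0.5))

    def slot_centers(self) -> list[PointOfInterest]:
        """Slot centres ``((2i+1) * canvas / (2 * side), ...)`` rounded to
        integer pixels, row-major."""
        side = self.grid_side
        pos = [int(round((2 * i + 1) * self.canvas / (2 * side))) for i in range(side)]
        return [PointOfInterest(x, y) for x in pos for y in pos]

    @property
    def slot_spacing(self) -> float:
        return self.canvas / self.grid_side


# ---------------------------------------------------------------------------
# icon painters
# ---------------------------------------------------------------------------


def _coords(size: int):
    c = (size - 1) / 2.0
    x = np.arange(size, dtype=np.float64)[:, None] - c
    y = np.arange(size, dtype=np.float64)[None, :] - c
    r = np.hypot(x, y)
    ang = np.arctan2(y, x)
    return x, y, r, ang


def _ellipse(rng, size):
    x, y, _, _ = _coords(size)
    R = 0.45 * size
    a = rng.uniform(0.80, 0.90) * R
    b = rng.uniform(0.45, 0.55) * R
    return (230.0 + rng.uniform(-10, 10)) * ((x / a) ** 2 + (y / b) ** 2 < 1.0)


def _triangle(rng, size):
    x, y, _, _ = _coords(size)
    R = 0.45 * size
    apex = rng.uniform(0.80, 0.90) * R
    base = rng.uniform(0.55, 0.70) * R
    inside = (x < apex) & (x > -0.55 * R) & (
        np.abs(y) < base * (apex - x) / (apex + 0.55 * R)
    )
    return 255.0 * inside


def _pacman(rng, size):
    _, _, r, ang = _coords(size)
    R = 0.45 * size
    mouth = np.deg2rad(rng.uniform(28, 38))
    return (210.0 + rng.uniform(-10, 10)) * ((r < 0.80 * R) & (np.abs(ang) > mouth))


def _dshape(rng, size):
    x, _, r, _ = _coords(size)
    R = 0.45 * size
    cut = rng.uniform(0.15, 0.25) * R
    return 245.0 * ((r < 0.80 * R) & (x > -cut))


def _teardrop(rng, size):
    x, y, _, _ = _coords(size)
    R = 0.45 * size
    rad = rng.uniform(0.50, 0.58) * R
    disk = np.hypot(x + 0.20 * R, y) < rad
    apex = rng.uniform(0.80, 0.90) * R
    tail = (x > -0.20 * R) & (x < apex) & (
        np.abs(y) < rad * (apex - x) / (apex + 0.20 * R)
    )
    return 200.0 * (disk | tail)


def _tee(rng, size):
    x, y, _, _ = _coords(size)
    R = 0.45 * size
    barw = rng.uniform(0.24, 0.30) * R
    top = (x > -0.85 * R) & (x < -0.85 * R + 2 * barw) & (np.abs(y) < 0.80 * R)
    stem = (np.abs(y) < barw) & (x >= -0.85 * R) & (x < 0.85 * R)
    return (250.0 + rng.uniform(-8, 8)) * (top | stem)


def _donut(rng, size):
    x, y, r, _ = _coords(size)
    R = 0.45 * size
    hole_off = rng.uniform(0.22, 0.30) * R
    hole = np.hypot(x - hole_off, y) < rng.uniform(0.26, 0.32) * R
    return 220.0 * ((r < 0.80 * R) & ~hole)


def _notched_block(rng, size):
    x, y, _, _ = _coords(size)
    R = 0.45 * size
    block = (np.abs(x) < 0.58 * R) & (np.abs(y) < rng.uniform(0.78, 0.88) * R)
    notch = (x < -0.58 * R + rng.uniform(0.45, 0.55) * R) & (y > 0.30 * R)
    return 235.0 * (block & ~notch)


def _crescent(rng, size):
    x, y, r, _ = _coords(size)
    R = 0.45 * size
    off = rng.uniform(0.30, 0.38) * R
    inner = np.hypot(x - off, y) < rng.uniform(0.48, 0.55) * R
    return 225.0 * ((r < 0.78 * R) & ~inner)


_PAINTERS = (
    _ellipse,
    _triangle,
    _pacman,
    _dshape,
    _teardrop,
    _tee,
    _donut,
    _notched_block,
    _crescent,
)


def _paint_icons(n: int, size: int, rng) -> list[np.ndarray]:
    icons = []
    for k in range(n):
        painter = _PAINTERS[k % len(_PAINTERS)]
        img = painter(rng, size)
        img = gaussian_filter(img, 1.0)  # soften edges for stable resampling
        icons.append(np.clip(img, 0.0, 255.0))
    return icons


def _icon_descriptor(icon: np.ndarray, frame: int) -> Descriptor:
    """Descriptor of an icon centred in a frame-by-frame black image."""
    const = prep_step(frame)
    f = np.zeros((frame, frame))
    h, w = icon.shape
    top, left = (frame - h) // 2, (frame - w) // 2
    f[top : top + h, left : left + w] = icon
    return comp_desc(f, frame // 2, frame // 2, const, default_beta(frame))


def icon_separation(icons: Sequence[np.ndarray], frame: int = 150) -> tuple[float, float]:
    """(min inter-icon distance, max icon-to-own-30deg-rotation distance).

    Distances are squared Euclidean between descriptors of icons centred
    in a frame-by-frame window — the quantity retrieval actually ranks.
    """
    descs = [_icon_descriptor(ic, frame) for ic in icons]
    rot_descs = [
        _icon_descriptor(
            rotate(ic, 30.0, resize=False, order=1, cval=0.0, preserve_range=True),
            frame,
        )
        for ic in icons
    ]
    inter = min(
        float(((a.v - b.v) ** 2).sum())
        for i, a in enumerate(descs)
        for b in descs[i + 1 :]
    )
    self_rot = max(
        float(((a.v - b.v) ** 2).sum()) for a, b in zip(descs, rot_descs)
    )
    return inter, self_rot


def make_icons(
    n: int = 9, size: int = 60, seed: int = 0, *, frame: int = 150, max_attempts: int = 5
) -> list[np.ndarray]:
    """Generate ``n`` distinct gray-scale icon images deterministically.

    The icons must satisfy the separation criterion (pairwise descriptor
    distance > 10x the worst own-rotation distance); shape parameters are
    re-jittered up to ``max_attempts`` times before giving up.
    """
    if n < 2:
        raise ConfigurationError(f"need at least 2 icons, got {n}")
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        icons = _paint_icons(n, size, rng)
        inter, self_rot = icon_separation(icons, frame)
        if inter > 10.0 * self_rot:
            return icons
    raise GenerationError(
        f"could not generate {n} separable icons in {max_attempts} attempts "
        f"(last inter={inter:.3g}, self-rotation={self_rot:.3g})"
    )


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------


def transform_icon(icon: np.ndarray, angle: float, scale: float) -> np.ndarray:
    """Scale then rotate an icon (bilinear, zero fill, in-place frame)."""
    img = icon
    if scale != 1.0:
        img = rescale(img, scale, order=1, anti_aliasing=False, preserve_range=True)
    if angle % 360 != 0.0:
        img = rotate(img, angle, resize=False, order=1, cval=0.0, preserve_range=True)
    return np.clip(img, 0.0, 255.0)


def build_dataset(
    spec: DatasetSpec,
) -> tuple[list[DensityImage], pd.DataFrame, list[DensityImage]]:
    """Build canvases, ground truth and query images for a spec.

    Every (icon, angle, scale) combination is placed exactly once; the
    assignment of combinations to (canvas, slot) pairs is a seeded
    permutation.  Returns ``(canvases, truth, queries)`` where ``truth``
    has one row per placement with columns
    ``canvas, x, y, icon, angle, scale``.
    """
    icons = make_icons(spec.n_icons, spec.icon_size, spec.seed, frame=spec.frame)
    centers = spec.slot_centers()
    combos = [
        (c, a, s)
        for c in range(spec.n_icons)
        for a in spec.angles
        for s in spec.scales
    ]
    rng = np.random.default_rng([spec.seed, 1000])
    slot_order = rng.permutation(spec.slots * spec.n_canvases)[: len(combos)]
    canvases = [np.zeros((spec.canvas, spec.canvas)) for _ in range(spec.n_canvases)]
    records = []
    for (icon_id, angle, scale), slot in zip(combos, slot_order):
        sub = transform_icon(icons[icon_id], angle, scale)
        h, w = sub.shape
        if max(h, w) > spec.slot_spacing:
            raise GenerationError(
                f"transformed icon ({h}x{w}) exceeds slot spacing "
                f"{spec.slot_spacing:.1f}"
            )
        canvas_id, local = divmod(int(slot), spec.slots)
        cx, cy = centers[local]
        top, left = cx - h // 2, cy - w // 2
        canvases[canvas_id][top : top + h, left : left + w] = sub
        records.append(
            {"canvas": f"db{canvas_id}", "x": cx, "y": cy, "icon": icon_id,
             "angle": angle, "scale": scale}
        )
    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    canvas_imgs = [
        DensityImage(c, image_id=f"db{i}") for i, c in enumerate(canvases)
    ]
    queries = []
    for k, icon in enumerate(icons):
        f = np.zeros((spec.frame, spec.frame))
        h, w = icon.shape
        top, left = (spec.frame - h) // 2, (spec.frame - w) // 2
        f[top : top + h, left : left + w] = icon
        queries.append(DensityImage(f, image_id=f"query{k}"))
    return canvas_imgs, truth, queries


def add_salt_pepper(f: DensityImage, density: float, seed) -> DensityImage:
    """Degrade a fraction ``density`` of pixels to extreme black/white.

    Pixels are chosen uniformly without replacement; each chosen pixel is
    set to 0 or 255 with equal probability.  ``seed`` may be an int, a
    sequence of ints, or a Generator.
    """
    if not 0.0 <= density <= 1.0:
        raise ConfigurationError(f"density must be in [0, 1], got {density}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = f.pixels.copy()
    n = int(round(density * out.size))
    if n:
        idx = rng.choice(out.size, size=n, replace=False)
        out.flat[idx] = rng.choice([0.0, 255.0], size=n)
    return DensityImage(out, image_id=f.image_id)


# ---------------------------------------------------------------------------
# scoring and the end-to-end benchmark
# ---------------------------------------------------------------------------


@dataclass
class ScoreReport:
    """Hit counts of a retrieval run against the ground truth."""

    top1_hits: int
    topk_hits: int
    n_queries: int
    k: int

    @property
    def top1(self) -> float:
        return self.top1_hits / self.n_queries

    @property
    def topk(self) -> float:
        return self.topk_hits / (self.n_queries * self.k)


def score_retrieval(
    results: Sequence[SearchResult],
    query_classes: Sequence[int],
    truth: pd.DataFrame,
    k: int,
    max_center_offset: float | None = None,
) -> ScoreReport:
    """Score ranked retrievals: a hit is a retrieval of the query's class.

    Each retrieved point is mapped to the nearest ground-truth slot
    centre of its canvas; a point farther than ``max_center_offset``
    (default: half the minimal centre spacing) indicates an index/truth
    mismatch and raises.
    """
    trees = {}
    classes = {}
    for canvas, grp in truth.groupby("canvas"):
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        trees[canvas] = cKDTree(pts)
        classes[canvas] = grp["icon"].to_numpy()
    if max_center_offset is None:
        spacing = min(
            float(t.query(t.data, k=2)[0][:, 1].min()) for t in trees.values()
        )
        max_center_offset = spacing / 2.0
    top1 = 0
    topk = 0
    for res, qclass in zip(results, query_classes):
        rows = res.ranked.head(k)
        for rank, row in enumerate(rows.itertuples(index=False)):
            if row.image_id not in trees:
                raise ConfigurationError(
                    f"retrieved image {row.image_id!r} absent from ground truth"
                )
            dist, j = trees[row.image_id].query([float(row.x_p), float(row.y_p)])
            if dist > max_center_offset:
                raise ConfigurationError(
                    f"retrieved point ({row.x_p}, {row.y_p}) is {dist:.1f} px "
                    "from the nearest slot centre — index/truth mismatch"
                )
            if classes[row.image_id][j] == qclass:
                topk += 1
                if rank == 0:
                    top1 += 1
    return ScoreReport(
        top1_hits=top1, topk_hits=topk, n_queries=len(results), k=k
    )


def run_experiment(
    spec: DatasetSpec,
    noise_density: float = 0.0,
    *,
    k: int = 5,
    beta: float | None = None,
) -> ScoreReport:
    """Full pipeline: build dataset, (optionally) degrade, index, search, score.

    Canvases are indexed at the slot centres with ``S = spec.frame``; the
    centred icon frames are the queries.  A nonzero ``noise_density``
    degrades the *whole dataset* — database canvases and query frames
    alike, each with an independent seeded noise realization — matching a
    retrieval-under-degradation protocol in which both sides of the
    comparison come from the corrupted data.
    """
    canvases, truth, queries = build_dataset(spec)
    if noise_density > 0.0:
        tag = int(round(noise_density * 1000))
        canvases = [
            add_salt_pepper(c, noise_density, [spec.seed, 101 + i, tag])
            for i, c in enumerate(canvases)
        ]
        queries = [
            add_salt_pepper(q, noise_density, [spec.seed, 501 + i, tag])
            for i, q in enumerate(queries)
        ]
    centers = spec.slot_centers()
    index = db_index(
        canvases, spec.frame, pois=[centers] * len(canvases), beta=beta
    )
    const = prep_step(spec.frame)
    results = []
    for q in queries:
        d = comp_desc(
            q, spec.frame // 2, spec.frame // 2, const,
            beta if beta is not None else default_beta(spec.frame),
            image_id=q.image_id,
        )
        results.append(db_search(d, index, k=k))
    return score_retrieval(results, list(range(len(queries))), truth, k=k)
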