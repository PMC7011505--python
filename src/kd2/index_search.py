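"""Offline database indexing and ranked subimage retrieval.

An index is a flat table with one row per described subimage,
``<image_id, x_p, y_p, Q20, Q02, Q12, Q21, Q30, Q03>``, plus the metadata
(window size ``S``, reference mass ``beta``, point-enumeration mode)
needed to guarantee that query descriptors are comparable.  Retrieval
ranks rows by the squared Euclidean distance

    d(V_Q, V_DB) = sum_i (V_Q[i] - V_DB[i])^2

between raw descriptor vectors.  Indexing only needs to run once per
database; searching is a single vectorized scan.

For noisy images with large uninformative areas (e.g. cryo-EM
micrographs), a variance pre-filter discards candidate points whose
local window has lower pixel variance than the image as a whole, keeping
only regions with visible structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .basis import prep_step
from .descriptor import COMPONENT_NAMES, Descriptor, comp_desc, default_beta
from .errors import ConfigurationError, DegenerateRegionError
from .image_io import DensityImage, PointOfInterest, square_crop

logger = logging.getLogger(__name__)

_COLUMNS = ["image_id", "x_p", "y_p", *COMPONENT_NAMES]


@dataclass
class IndexTable:
    """Descriptor rows for every indexed subimage, plus provenance."""

    table: pd.DataFrame
    meta: dict

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SearchResult:
    """Rows ranked by ascending descriptor distance to a query."""

    ranked: pd.DataFrame  # _COLUMNS + "distance"
    truncated: bool = False  # True when fewer rows than requested exist


def grid_centers(N: int, M: int, stride: int) -> list[PointOfInterest]:
    """Regular grid of candidate points with the given stride.

    Cell centres of a stride-by-stride tiling: ``floor(N/stride) *
    floor(M/stride)`` points in row-major order.
    """
    if stride < 1:
        raise ConfigurationError(f"stride must be positive, got {stride}")
    return [
        PointOfInterest(i * stride + stride // 2, j * stride + stride // 2)
        for i in range(N // stride)
        for j in range(M // stride)
    ]


def local_variance_filter(
    f: DensityImage, centers: Sequence[PointOfInterest], window: int
) -> list[PointOfInterest]:
    """Keep centres whose local window variance reaches the global variance.

    Both sides use the population variance (divide by the pixel count).
    The window around each centre is clamped inside the image exactly as
    :func:`kd2.image_io.square_crop` clamps crops.  On a constant image
    every centre is kept (0 >= 0).  Input order is preserved.
    """
    N, M = f.pixels.shape
    if window > min(N, M):
        raise ConfigurationError(
            f"filter window {window} exceeds image dimensions {N}x{M}"
        )
    global_var = float(f.pixels.var())
    kept = []
    for c in centers:
        r0 = min(max(int(c[0]) - window // 2, 0), N - window)
        c0 = min(max(int(c[1]) - window // 2, 0), M - window)
        local = f.pixels[r0 : r0 + window, c0 : c0 + window]
        if float(local.var()) >= global_var:
            kept.append(c)
    return kept


def db_index(
    images: Iterable[DensityImage],
    S: int,
    *,
    pois: Sequence[Sequence[PointOfInterest]] | None = None,
    stride: int | None = None,
    beta: float | None = None,
    variance_filter: bool = False,
    filter_window: int = 40,
) -> IndexTable:
    """Produce descriptors for all candidate subimages of a database.

    Candidate points come either from an explicit per-image list
    (``pois``) or from a regular grid (``stride``); exactly one of the
    two must be given.  Degenerate (blank) points are skipped with a
    warning.  Row order is deterministic: image order, then the given /
    row-major point order.
    """
    images = list(images)
    if not images:
        raise ConfigurationError("empty image database")
    if (pois is None) == (stride is None):
        raise ConfigurationError("provide exactly one of pois= or stride=")
    if pois is not None and len(pois) != len(images):
        raise ConfigurationError(
            f"{len(pois)} point lists for {len(images)} images"
        )
    if beta is None:
        beta = default_beta(S)
    const = prep_step(S)
    rows = []
    for i, img in enumerate(images):
        if S > min(img.n_rows, img.n_cols):
            raise ConfigurationError(
                f"window {S} exceeds image {img.image_id!r} "
                f"({img.n_rows}x{img.n_cols})"
            )
        centers = (
            list(pois[i])
            if pois is not None
            else grid_centers(img.n_rows, img.n_cols, stride)
        )
        if len(set(map(tuple, centers))) != len(centers):
            raise ConfigurationError(
                f"duplicate points of interest for image {img.image_id!r}"
            )
        if variance_filter:
            centers = local_variance_filter(img, centers, filter_window)
        produced = 0
        for c in centers:
            win, x_s, y_s = square_crop(img, PointOfInterest(*c), S)
            try:
                d = comp_desc(
                    win, x_s, y_s, const, beta,
                    image_id=img.image_id or f"image{i}", poi=(c[0], c[1]),
                )
            except DegenerateRegionError:
                logger.warning(
                    "skipping blank point (%d, %d) of image %r", c[0], c[1],
                    img.image_id,
                )
                continue
            rows.append(d.as_row())
            produced += 1
        if produced == 0:
            logger.warning("image %r produced no index rows", img.image_id)
    table = pd.DataFrame(rows, columns=_COLUMNS)
    meta = {
        "S": S,
        "beta": float(beta),
        "mode": "poi" if pois is not None else "grid",
        "stride": stride if stride is not None else 0,
        "variance_filter": bool(variance_filter),
        "filter_window": filter_window,
    }
    return IndexTable(table=table, meta=meta)


def descriptor_distance(a: Descriptor, b: Descriptor) -> float:
    """Squared Euclidean distance between two descriptor vectors."""
    if a.S != b.S or a.beta != b.beta:
        raise ConfigurationError(
            f"descriptors not comparable: S/beta ({a.S}, {a.beta}) vs "
            f"({b.S}, {b.beta})"
        )
    diff = a.v - b.v
    return float(diff @ diff)


def db_search(query: Descriptor, index: IndexTable, k: int = 5) -> SearchResult:
    """Rank index rows by squared Euclidean distance to ``query``.

    Ties are broken deterministically by ``(image_id, x_p, y_p)``, so the
    result does not depend on index insertion order.  If ``k`` exceeds
    the table size, all rows are returned and the result is flagged
    ``truncated``.
    """
    if len(index) == 0:
        raise ConfigurationError("cannot search an empty index")
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if query.S != index.meta["S"] or query.beta != index.meta["beta"]:
        raise ConfigurationError(
            f"query (S={query.S}, beta={query.beta}) does not match index "
            f"(S={index.meta['S']}, beta={index.meta['beta']})"
        )
    vals = index.table[list(COMPONENT_NAMES)].to_numpy()
    dist = ((vals - query.v) ** 2).sum(axis=1)
    ranked = index.table.assign(distance=dist).sort_values(
        ["distance", "image_id", "x_p", "y_p"], kind="mergesort"
    )
    truncated = k > len(ranked)
    return SearchResult(
        ranked=ranked.head(k).reset_index(drop=True), truncated=truncated
    )


def write_index(index: IndexTable, path) -> None:
    """Serialize an index as TSV with ``#``-prefixed metadata header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# kd2-index v1\n")
        for key in ("S", "beta", "mode", "stride", "variance_filter", "filter_window"):
            fh.write(f"# {key}={index.meta[key]}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for row in index.table.itertuples(index=False):
            vals = "\t".join(f"{getattr(row, c):.8g}" for c in COMPONENT_NAMES)
            fh.write(f"{row.image_id}\t{row.x_p}\t{row.y_p}\t{vals}\n")


def read_index(path) -> IndexTable:
    """Load an index written by :func:`write_index`."""
    path = Path(path)
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# kd2-index"):
            raise ConfigurationError(f"{path} is not a kd2 index file")
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    meta = {
        "S": int(meta["S"]),
        "beta": float(meta["beta"]),
        "mode": meta["mode"],
        "stride": int(meta["stride"]),
        "variance_filter": meta["variance_filter"] == "True",
        "filter_window": int(meta["filter_window"]),
    }
    table["image_id"] = table["image_id"].astype(str)
    return IndexTable(table=table[_COLUMNS], meta=meta)
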