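"""Segmentation: broccoli vs background, floret vs stem, and spectral
down-sampling.

Foreground extraction is a 2-cluster k-means on preprocessed spectra with
the vegetation cluster identified by a green-bump score, followed by
morphological closing. Floret extraction is a deterministic seeded min-cut
on the 4-connected pixel graph (a reproducible replacement for an
interactive graph-cut tool). Down-sampling compresses a sample's spectra
to a fixed budget of k-means cluster means.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.morphology import disk
from sklearn.cluster import KMeans, MiniBatchKMeans

from .core import (
    DegenerateDataError,
    HyperCube,
    InvalidParameterError,
    Mask,
    SpectraMatrix,
)

__all__ = [
    "green_bump_score",
    "kmeans_foreground",
    "morphological_close",
    "seeded_floret_segment",
    "downsample_spectra",
]

log = logging.getLogger(__name__)

GREEN_WINDOW = (540.0, 560.0)
RED_WINDOW = (620.0, 680.0)


def green_bump_score(spectrum: np.ndarray, grid) -> float:
    """Mean reflectance in 540-560 nm minus mean in 620-680 nm.

    Vegetation (green bump plus chlorophyll absorption) scores higher than
    the flat-then-rising dark background.
    """
    g = grid.band_slice(*GREEN_WINDOW)
    r = grid.band_slice(*RED_WINDOW)
    if not g.any() or not r.any():
        raise InvalidParameterError("grid does not cover the scoring windows")
    s = np.asarray(spectrum, dtype=float)
    return float(s[g].mean() - s[r].mean())


def kmeans_foreground(spectra: SpectraMatrix, seed: int = 0,
                      n_init: int = 10) -> Mask:
    """2-means the preprocessed spectra and return the broccoli mask.

    The broccoli cluster is the one whose centroid has the higher
    green-bump score; a near-tie (no vegetation-like cluster) raises.
    """
    if spectra.pixel_index is None or spectra.image_shape is None:
        raise InvalidParameterError("spectra must carry pixel_index and image_shape")
    unique = np.unique(spectra.values, axis=0)
    if unique.shape[0] < 2:
        raise DegenerateDataError("need at least 2 distinct spectra for 2-means")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(spectra.values)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("k-means produced an empty cluster")
    scores = [green_bump_score(c, spectra.grid) for c in km.cluster_centers_]
    gap = abs(scores[0] - scores[1])
    scale = float(np.abs(spectra.values).mean()) or 1.0
    if max(scores) <= 0 or gap < 1e-3 * scale:
        raise DegenerateDataError(
            "low-confidence broccoli/background split: no cluster shows a "
            f"green-bump signature (scores {scores[0]:.4g}, {scores[1]:.4g})"
        )
    broccoli = int(np.argmax(scores))
    values = np.zeros(spectra.image_shape, dtype=np.uint8)
    sel = labels == broccoli
    values[spectra.pixel_index[sel, 0], spectra.pixel_index[sel, 1]] = 1
    return Mask(values=values, role="foreground")


def morphological_close(mask: Mask, radius: int = 2) -> Mask:
    """Dilation then erosion with a disk structuring element."""
    if radius < 0:
        raise InvalidParameterError("radius must be >= 0")
    if radius == 0:
        return Mask(values=mask.values.copy(), role=mask.role)
    footprint = disk(radius).astype(bool)
    # dilation sees the outside as background, erosion as foreground, so
    # closing never erodes the image border
    dilated = binary_dilation(mask.values.astype(bool), structure=footprint)
    closed = binary_erosion(dilated, structure=footprint, border_value=1)
    return Mask(values=closed.astype(np.uint8), role=mask.role)


def seeded_floret_segment(
    cube: HyperCube,
    fg_mask: Mask,
    floret_seeds: Sequence[Tuple[int, int]],
    stem_seeds: Sequence[Tuple[int, int]],
    beta: Optional[float] = None,
) -> Mask:
    """Deterministic seeded min-cut separating floret from stem.

    Builds a 4-connected graph over foreground pixels with edge weights
    exp(-beta * ||s_u - s_v||^2); seeds are hard-constrained via
    large-capacity terminal edges. beta defaults to
    1 / (2 * mean squared spectral edge difference).
    """
    floret_seeds = [tuple(s) for s in floret_seeds]
    stem_seeds = [tuple(s) for s in stem_seeds]
    if not floret_seeds or not stem_seeds:
        raise InvalidParameterError("both seed sets must be nonempty")
    if set(floret_seeds) & set(stem_seeds):
        raise InvalidParameterError("seed sets must be disjoint")
    fg = fg_mask.values.astype(bool)
    if fg.shape != cube.shape[:2]:
        raise InvalidParameterError("mask shape must match cube")
    for (y, x) in floret_seeds + stem_seeds:
        if not (0 <= y < fg.shape[0] and 0 <= x < fg.shape[1]) or not fg[y, x]:
            raise InvalidParameterError(f"seed ({y}, {x}) outside the foreground mask")

    coords = np.argwhere(fg)
    # pairwise spectral differences along 4-connected foreground edges
    edges = []
    diffs = []
    fgset = {tuple(c) for c in map(tuple, coords)}
    for (y, x) in map(tuple, coords):
        for (dy, dx) in ((0, 1), (1, 0)):
            v = (y + dy, x + dx)
            if v in fgset:
                d = cube.data[y, x] - cube.data[v]
                edges.append(((y, x), v))
                diffs.append(float(np.dot(d, d)))
    diffs = np.asarray(diffs)
    if beta is None:
        mean_sq = diffs.mean() if diffs.size else 1.0
        beta = 1.0 / (2.0 * mean_sq) if mean_sq > 0 else 1.0

    g = nx.Graph()
    weights = np.exp(-beta * diffs) + 1e-9
    for (u, v), wgt in zip(edges, weights):
        g.add_edge(u, v, capacity=float(wgt))
    big = float(weights.sum() + 1.0)
    for s in floret_seeds:
        g.add_edge("SRC", s, capacity=big)
    for s in stem_seeds:
        g.add_edge(s, "SNK", capacity=big)
    _, (src_side, _) = nx.minimum_cut(g, "SRC", "SNK")
    values = np.zeros_like(fg, dtype=np.uint8)
    for node in src_side:
        if node != "SRC":
            values[node] = 1
    values &= fg.astype(np.uint8)
    return Mask(values=values, role="floret")


def downsample_spectra(spectra: SpectraMatrix, budget: int = 5000,
                       seed: int = 0, max_iter: int = 30) -> SpectraMatrix:
    """Compress N spectra to exactly min(N, budget) k-means cluster means.

    Cluster means are exact partition means of the inputs (so total spectral
    mass is conserved); empty clusters are re-seeded with points stolen from
    multi-member clusters until the representative count is exact.
    """
    if budget < 1:
        raise InvalidParameterError("budget must be >= 1")
    n = spectra.n_spectra
    if n <= budget:
        return spectra
    x = spectra.values
    if budget == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = MiniBatchKMeans(
            n_clusters=budget,
            random_state=seed,
            batch_size=max(1024, 4 * budget // 3),
            n_init=1,
            max_iter=max_iter,
            max_no_improvement=5,
        )
        labels = km.fit(x).labels_.copy()
    labels = _fill_empty_clusters(x, labels, budget)
    means = np.zeros((budget, x.shape[1]))
    np.add.at(means, labels, x)
    counts = np.bincount(labels, minlength=budget)
    means /= counts[:, None]
    return SpectraMatrix(values=means, grid=spectra.grid,
                         image_shape=spectra.image_shape)


def _fill_empty_clusters(x: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Move one point into each empty cluster, taken from the cluster whose
    member is currently farthest from its own mean."""
    counts = np.bincount(labels, minlength=k)
    empty = list(np.where(counts == 0)[0])
    if not empty:
        return labels
    log.debug("re-seeding %d empty down-sampling clusters", len(empty))
    for cluster in empty:
        donors = np.where(counts >= 2)[0]
        # farthest point from its cluster mean among donor clusters
        best_row, best_dist = -1, -1.0
        for d in donors:
            rows = np.where(labels == d)[0]
            mean = x[rows].mean(axis=0)
            dist = np.linalg.norm(x[rows] - mean, axis=1)
            j = int(np.argmax(dist))
            if dist[j] > best_dist:
                best_dist, best_row = float(dist[j]), rows[j]
        if best_row < 0:  # all donors are singletons: steal any singleton
            best_row = int(np.argmax(counts[labels] >= 1))
        counts[labels[best_row]] -= 1
        labels[best_row] = cluster
        counts[cluster] += 1
    return labels
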