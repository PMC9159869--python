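"""From filtered modes to a final region partition.

Post-processing runs in four stages, in order:

1. ``label_modes``       -- connected components of near-equal mode gray.
2. ``merge_regions``     -- threshold merging: while the smallest
   absolute difference of adjacent region mean grays is <= H, merge that
   pair and recompute the mean.
3. ``merge_nonprotruding`` -- a region whose mode density is small
   relative to the strongest adjacent mode is absorbed by that
   neighbour.
4. ``remove_fragments``  -- regions below a pixel-count floor join the
   adjacent region with the closest mean gray.

Every stage maps a partition to a coarser (or equal) partition; the
region count never increases.  All tie-breaks are by label order so a
fixed input yields a fixed output.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .image_io import GrayImage, LabelMap
from .meanshift import ModeMap, kde_values

DEFAULT_GRAY_TOL = 1.0
DEFAULT_CONNECTIVITY = 4
DEFAULT_MIN_SIZE = 20
DEFAULT_PROMINENCE = 0.3


@dataclass(frozen=True)
class RegionAdjacency:
    """Region statistics plus the adjacency structure of a LabelMap."""

    regions: tuple[tuple[int, int, float], ...]  # (label, pixel count, mean gray)
    edges: frozenset[tuple[int, int]]


def _neighbor_pairs(shape: tuple[int, int], connectivity: int):
    """Index pairs of neighbouring pixels (flat indices) for 4- or 8-connectivity."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    pairs = [
        (idx[:, :-1].ravel(), idx[:, 1:].ravel()),
        (idx[:-1, :].ravel(), idx[1:, :].ravel()),
    ]
    if connectivity == 8:
        pairs.append((idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()))
        pairs.append((idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()))
    a = np.concatenate([p[0] for p in pairs])
    b = np.concatenate([p[1] for p in pairs])
    return a, b


def label_modes(
    modes: ModeMap,
    gray_tol: float = DEFAULT_GRAY_TOL,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> LabelMap:
    """Group neighbouring pixels whose converged grays differ by <= gray_tol.

    Connected components of that pixel graph become regions, labelled
    1..K in raster order of first occurrence.
    """
    if gray_tol <= 0:
        raise ValueError("gray_tol must be positive")
    mg = modes.mode_gray
    h, w = mg.shape
    a, b = _neighbor_pairs((h, w), connectivity)
    flat = mg.ravel()
    keep = np.abs(flat[a] - flat[b]) <= gray_tol
    graph = coo_matrix(
        (np.ones(int(keep.sum())), (a[keep], b[keep])), shape=(h * w, h * w)
    )
    _, comp = connected_components(graph, directed=False)
    # relabel components 1..K in raster order of first appearance
    _, first = np.unique(comp, return_index=True)
    order = np.argsort(first)
    lut = np.empty(len(order), dtype=np.int64)
    lut[order] = np.arange(1, len(order) + 1)
    return LabelMap(lut[comp].reshape(h, w))


def region_adjacency(labels: LabelMap, img: GrayImage, connectivity: int = 4) -> RegionAdjacency:
    """Region sizes, mean grays and the set of adjacent label pairs."""
    lab = labels.labels
    counts = np.bincount(lab.ravel())
    sums = np.bincount(lab.ravel(), weights=img.pixels.ravel())
    regions = tuple(
        (int(l), int(counts[l]), float(sums[l] / counts[l]))
        for l in np.unique(lab)
        if l > 0
    )
    a, b = _neighbor_pairs(lab.shape, connectivity)
    la, lb = lab.ravel()[a], lab.ravel()[b]
    diff = la != lb
    pairs = np.stack([np.minimum(la[diff], lb[diff]), np.maximum(la[diff], lb[diff])], 1)
    edges = frozenset((int(x), int(y)) for x, y in np.unique(pairs, axis=0))
    return RegionAdjacency(regions, edges)


class _RegionGraph:
    """Mutable region statistics + adjacency with union merging."""

    def __init__(self, labels: LabelMap, img: GrayImage, connectivity: int = 4):
        lab = labels.labels
        self.shape = lab.shape
        self.lab = lab.copy()
        self.count = {}
        self.graysum = {}
        counts = np.bincount(lab.ravel())
        sums = np.bincount(lab.ravel(), weights=img.pixels.ravel())
        for l in np.unique(lab):
            if l > 0:
                self.count[int(l)] = int(counts[l])
                self.graysum[int(l)] = float(sums[l])
        self.adj: dict[int, set[int]] = {l: set() for l in self.count}
        a, b = _neighbor_pairs(lab.shape, connectivity)
        la, lb = lab.ravel()[a], lab.ravel()[b]
        diff = la != lb
        for x, y in np.unique(
            np.stack([np.minimum(la[diff], lb[diff]), np.maximum(la[diff], lb[diff])], 1),
            axis=0,
        ):
            self.adj[int(x)].add(int(y))
            self.adj[int(y)].add(int(x))
        # union-find over labels
        self.parent = {l: l for l in self.count}

    def find(self, l: int) -> int:
        while self.parent[l] != l:
            self.parent[l] = self.parent[self.parent[l]]
            l = self.parent[l]
        return l

    def mean(self, l: int) -> float:
        return self.graysum[l] / self.count[l]

    def merge(self, a: int, b: int) -> int:
        """Absorb region b into region a (both must be roots)."""
        self.parent[b] = a
        self.count[a] += self.count.pop(b)
        self.graysum[a] += self.graysum.pop(b)
        nb = self.adj.pop(b)
        nb.discard(a)
        self.adj[a].discard(b)
        for x in nb:
            self.adj[x].discard(b)
            self.adj[x].add(a)
            self.adj[a].add(x)
        return a

    def to_label_map(self) -> LabelMap:
        maxl = int(self.lab.max())
        lut = np.arange(maxl + 1, dtype=np.int64)
        for l in list(np.unique(self.lab)):
            if l > 0:
                lut[l] = self.find(int(l))
        return LabelMap(lut[self.lab]).compacted()


def merge_regions(
    labels: LabelMap,
    img: GrayImage,
    H: float,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> LabelMap:
    """Merge adjacent regions whose mean-gray difference is <= H.

    Globally smallest difference first; region means are recomputed
    after every merge, so a merge can enable or disable later ones.
    Ties break on the (smaller, larger) label pair.
    """
    if H <= 0:
        raise ValueError("H must be positive")
    g = _RegionGraph(labels, img, connectivity)
    heap = []
    for a in g.adj:
        for b in g.adj[a]:
            if a < b:
                heapq.heappush(heap, (abs(g.mean(a) - g.mean(b)), a, b))
    while heap:
        d, a, b = heapq.heappop(heap)
        ra, rb = -1, -1
        if a in g.count and b in g.count and b in g.adj[a]:
            ra, rb = a, b
        else:
            continue
        # stale entry if means moved since push
        cur = abs(g.mean(ra) - g.mean(rb))
        if cur != d:
            if cur <= H:
                heapq.heappush(heap, (cur, ra, rb))
            continue
        if d > H:
            break
        keep = g.merge(min(ra, rb), max(ra, rb))
        for x in sorted(g.adj[keep]):
            pair = (min(keep, x), max(keep, x))
            heapq.heappush(heap, (abs(g.mean(keep) - g.mean(x)), *pair))
    return g.to_label_map()


def region_mode_density(labels: LabelMap, modes: ModeMap, img: GrayImage) -> dict[int, float]:
    """Peak joint-KDE value over each region's converged points.

    The density of the underlying image samples, evaluated where a
    region's pixels came to rest, measures how strongly that mode
    protrudes from the kernel density surface; the region's mode height
    is the maximum over its members (regions need not be convex, so no
    single averaged point can represent them).
    """
    lab = labels.labels.ravel()
    pts = np.stack(
        [
            modes.mode_pos[..., 0].ravel(),
            modes.mode_pos[..., 1].ravel(),
            modes.mode_gray.ravel(),
        ],
        axis=1,
    )
    dens = kde_values(img, pts, modes.params)
    out: dict[int, float] = {}
    for l in np.unique(lab):
        if l > 0:
            out[int(l)] = float(dens[lab == l].max())
    return out


def merge_nonprotruding(
    labels: LabelMap,
    modes: ModeMap,
    img: GrayImage,
    prominence: float = DEFAULT_PROMINENCE,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> LabelMap:
    """Absorb regions whose mode density is weak next to a stronger mode.

    A region with density d is absorbed into its densest adjacent
    region (density d_max) whenever d < prominence * d_max; repeated,
    weakest region first, until stable.
    """
    if not 0.0 < prominence < 1.0:
        raise ValueError("prominence must lie in (0, 1)")
    dens = region_mode_density(labels, modes, img)
    g = _RegionGraph(labels, img, connectivity)
    changed = True
    while changed:
        changed = False
        for l in sorted(g.count, key=lambda x: (dens[x], x)):
            if l not in g.count or not g.adj[l]:
                continue
            best = max(g.adj[l], key=lambda x: (dens[x], -x))
            if dens[l] < prominence * dens[best]:
                g.merge(best, l)
                # absorbed pixels now belong to the stronger mode
                changed = True
    return g.to_label_map()


def remove_fragments(
    labels: LabelMap,
    img: GrayImage,
    min_size: int = DEFAULT_MIN_SIZE,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> LabelMap:
    """Merge every region smaller than min_size into its closest-gray neighbour.

    Smallest fragment first; sizes and means update as merging
    proceeds.  If the whole image holds fewer than min_size pixels the
    single remaining region is kept.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    g = _RegionGraph(labels, img, connectivity)
    heap = [(n, l) for l, n in g.count.items() if n < min_size]
    heapq.heapify(heap)
    while heap:
        n, l = heapq.heappop(heap)
        if l not in g.count or g.count[l] != n or not g.adj[l]:
            continue  # stale entry, or isolated single-region image
        target = min(g.adj[l], key=lambda x: (abs(g.mean(x) - g.mean(l)), x))
        g.merge(target, l)
        if g.count[target] < min_size:
            heapq.heappush(heap, (g.count[target], target))
    return g.to_label_map()
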