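"""Multi-source least-cost connectivity machinery.

Movement cost is accumulated over the 8-neighbour cell lattice.  The edge
weight between adjacent cells a and b is the centre-to-centre distance
times the mean of the two cells' resistances:
``cell_size * (r_a + r_b) / 2``, with an extra sqrt(2) factor for diagonal
moves — the standard GIS cost-distance convention.  One cost unit (cu)
therefore equals one metre travelled through resistance-1 habitat, so a
dispersal bandwidth of 125,000 cu is 125 km through ideal habitat and
proportionately less through worse.

Three synoptic products are built on top of single-source shortest-path
trees (scipy's Dijkstra over the sparse lattice graph):

* cumulative resistant kernels — each source contributes a linear kernel
  ``max(0, 1 - c / bandwidth)`` of its least-cost distance field c, summed
  over sources; the kernel reaches zero exactly at the bandwidth, the
  species' maximum dispersal cost;
* factorial least-cost path density — one least-cost path is extracted for
  every unordered pair of sources (deterministic tie-breaking via the
  predecessor tree) and every cell on it counts 1;
* a circular focal mean for smoothing path-density surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .raster import RasterGrid, check_aligned
from .resistance import ResistanceGrid, SourcePointSet

__all__ = [
    "CostDistanceField",
    "KernelSurface",
    "PathDensitySurface",
    "build_lattice_graph",
    "cost_distance",
    "cumulative_resistant_kernel",
    "factorial_least_cost_paths",
    "pairwise_cost_matrix",
    "focal_mean",
    "allometric_max_dispersal",
]

_OFFSETS_8 = [
    (0, 1, 1.0),
    (1, 0, 1.0),
    (1, 1, math.sqrt(2.0)),
    (1, -1, math.sqrt(2.0)),
]
_OFFSETS_4 = [(0, 1, 1.0), (1, 0, 1.0)]


@dataclass
class LatticeGraph:
    """Sparse undirected graph over the valid cells of a resistance grid."""

    graph: "coo_matrix"  # CSR after construction
    node_of_cell: np.ndarray  # flat cell index -> node id, -1 for nodata
    cell_of_node: np.ndarray  # node id -> flat cell index
    shape: tuple[int, int]
    cell_size: float


def build_lattice_graph(r: ResistanceGrid, neighbors: int = 8) -> LatticeGraph:
    if neighbors not in (4, 8):
        raise ValueError("neighbors must be 4 or 8")
    values = np.asarray(r.raster.values, dtype=float)
    valid = r.raster.data_mask()
    rows, cols = values.shape
    node_of_cell = -np.ones(rows * cols, dtype=np.int64)
    cell_of_node = np.flatnonzero(valid.ravel())
    node_of_cell[cell_of_node] = np.arange(len(cell_of_node))

    cell = r.raster.cell_size
    offsets = _OFFSETS_8 if neighbors == 8 else _OFFSETS_4
    src_list, dst_list, w_list = [], [], []
    for dr, dc, dist in offsets:
        a = valid[max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)]
        b = valid[max(0, dr) : rows + min(0, dr), max(0, dc) : cols + min(0, dc)]
        ok = a & b
        ar, ac = np.nonzero(ok)
        ar = ar + max(0, -dr)
        ac = ac + max(0, -dc)
        br, bc = ar + dr, ac + dc
        wa = values[ar, ac]
        wb = values[br, bc]
        src_list.append(node_of_cell[ar * cols + ac])
        dst_list.append(node_of_cell[br * cols + bc])
        w_list.append(cell * dist * (wa + wb) / 2.0)
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    w = np.concatenate(w_list)
    n = len(cell_of_node)
    graph = coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()
    return LatticeGraph(graph, node_of_cell, cell_of_node, (rows, cols), cell)


def _source_nodes(lattice: LatticeGraph, sources: SourcePointSet) -> np.ndarray:
    flat = sources.points[:, 0] * lattice.shape[1] + sources.points[:, 1]
    nodes = lattice.node_of_cell[flat]
    if (nodes < 0).any():
        bad = sources.points[nodes < 0]
        raise ValueError(f"source points on nodata cells: {bad.tolist()[:5]}")
    return nodes


@dataclass
class CostDistanceField:
    """Accumulated least cost from one source, with back-pointers."""

    raster: RasterGrid  # accumulated cost, inf where unreached
    source: tuple[int, int]
    max_cost: float
    predecessors: np.ndarray  # flat cell index of predecessor, -1 at source/unreached


def cost_distance(
    r: ResistanceGrid,
    source: tuple[int, int],
    max_cost: float = np.inf,
    neighbors: int = 8,
) -> CostDistanceField:
    """Dijkstra cost-distance field from a single source cell."""
    lattice = build_lattice_graph(r, neighbors)
    rows, cols = lattice.shape
    sr, sc = source
    node = lattice.node_of_cell[sr * cols + sc]
    if node < 0:
        raise ValueError(f"source {source} is on a nodata cell")
    dist, pred = dijkstra(
        lattice.graph,
        directed=False,
        indices=node,
        limit=max_cost,
        return_predecessors=True,
    )
    field = np.full(rows * cols, np.inf)
    field[lattice.cell_of_node] = dist
    pred_cells = np.full(rows * cols, -1, dtype=np.int64)
    has_pred = pred >= 0
    pred_cells[lattice.cell_of_node[has_pred]] = lattice.cell_of_node[pred[has_pred]]
    return CostDistanceField(
        r.raster.copy(field.reshape(rows, cols)), source, max_cost, pred_cells
    )


@dataclass
class KernelSurface:
    """Cumulative expected disperser density (sum of per-source kernels)."""

    raster: RasterGrid
    bandwidth: float
    epoch_label: str = ""


def cumulative_resistant_kernel(
    r: ResistanceGrid,
    sources: SourcePointSet,
    bandwidth: float,
    neighbors: int = 8,
) -> KernelSurface:
    """Sum of linear resistant kernels over all source points.

    Each source starts with expected density 1 in its own cell and
    contributes ``max(0, 1 - c / bandwidth)`` in every cell with least cost
    c from it; sources sharing a cell add.
    """
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")
    if len(sources) == 0:
        raise ValueError("no source points")
    lattice = build_lattice_graph(r, neighbors)
    nodes = _source_nodes(lattice, sources)
    uniq, counts = np.unique(nodes, return_counts=True)
    surface = np.zeros(lattice.graph.shape[0])
    # chunk sources so the distance block stays modest in memory
    chunk = max(1, int(5e7 // max(1, lattice.graph.shape[0])))
    for start in range(0, len(uniq), chunk):
        idx = uniq[start : start + chunk]
        dist = dijkstra(lattice.graph, directed=False, indices=idx, limit=bandwidth)
        with np.errstate(invalid="ignore"):
            k = 1.0 - dist / bandwidth
        k[~np.isfinite(dist)] = 0.0
        np.clip(k, 0.0, None, out=k)
        surface += counts[start : start + chunk] @ k
    rows, cols = lattice.shape
    out = np.zeros(rows * cols)
    out[lattice.cell_of_node] = surface
    return KernelSurface(r.raster.copy(out.reshape(rows, cols)), bandwidth, r.epoch_label)


@dataclass
class PathDensitySurface:
    """Per-cell count (or smoothed density) of factorial least-cost paths."""

    raster: RasterGrid
    smoothed: bool = False
    radius: float = 0.0
    epoch_label: str = ""


def factorial_least_cost_paths(
    r: ResistanceGrid,
    sources: SourcePointSet,
    max_cost: float | None = None,
    neighbors: int = 8,
) -> PathDensitySurface:
    """Density of one least-cost path per unordered source pair.

    For each source, one Dijkstra tree is grown and the path to every
    higher-indexed source is read off the predecessor array; every cell on
    the path (endpoints included) is incremented by 1.  Pairs farther apart
    than ``max_cost`` (if given) contribute nothing.  Tie-breaking among
    equal-cost paths follows the deterministic order of the shortest-path
    tree construction, so repeated runs are identical.
    """
    if len(sources) < 2:
        raise ValueError("need at least 2 sources")
    limit = np.inf if max_cost is None else max_cost
    lattice = build_lattice_graph(r, neighbors)
    nodes = _source_nodes(lattice, sources)
    counts = np.zeros(lattice.graph.shape[0], dtype=np.int64)
    n = len(nodes)
    for i in range(n - 1):
        dist, pred = dijkstra(
            lattice.graph,
            directed=False,
            indices=nodes[i],
            limit=limit,
            return_predecessors=True,
        )
        for j in range(i + 1, n):
            tgt = nodes[j]
            if not np.isfinite(dist[tgt]):
                continue
            node = tgt
            while node >= 0 and node != nodes[i]:
                counts[node] += 1
                node = pred[node]
            counts[nodes[i]] += 1
    rows, cols = lattice.shape
    out = np.zeros(rows * cols, dtype=np.int64)
    out[lattice.cell_of_node] = counts
    return PathDensitySurface(
        r.raster.copy(out.reshape(rows, cols)), False, 0.0, r.epoch_label
    )


def pairwise_cost_matrix(
    r: ResistanceGrid,
    sources: SourcePointSet,
    max_cost: float = np.inf,
    neighbors: int = 8,
) -> np.ndarray:
    """Symmetric least-cost distance matrix between all source points.

    Entries beyond ``max_cost`` (or unreachable) are +inf.  Diagonal is 0.
    """
    lattice = build_lattice_graph(r, neighbors)
    nodes = _source_nodes(lattice, sources)
    dist = dijkstra(lattice.graph, directed=False, indices=nodes, limit=max_cost)
    return np.asarray(dist[:, nodes])


def focal_mean(surface: RasterGrid, radius: float) -> RasterGrid:
    """Circular focal mean: each cell becomes the mean over cells whose
    centre lies within ``radius`` metres (inclusive); at edges only the
    in-bounds part of the window is averaged.  Nodata cells are excluded
    from every window and stay nodata."""
    if radius < surface.cell_size:
        raise ValueError("radius must be at least one cell size")
    rc = radius / surface.cell_size
    k = int(math.floor(rc))
    dy, dx = np.mgrid[-k : k + 1, -k : k + 1]
    kernel = (dy**2 + dx**2) <= rc**2 + 1e-9
    valid = surface.data_mask()
    vals = np.where(valid, surface.values, 0.0).astype(float)
    sums = ndimage.convolve(vals, kernel.astype(float), mode="constant", cval=0.0)
    cnts = ndimage.convolve(valid.astype(float), kernel.astype(float), mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / cnts
    mean[~valid] = surface.nodata
    return surface.copy(mean)


def allometric_max_dispersal(home_range_km2: float) -> float:
    """Allometric bound on mammalian maximum dispersal distance (km):
    40 times the square root of home-range area in km^2."""
    if home_range_km2 < 0:
        raise ValueError("home range must be non-negative")
    return 40.0 * math.sqrt(home_range_km2)
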