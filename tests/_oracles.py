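"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
sums, depth-first search, batched multinomial sampling) so it shares no
code path with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

SQRT2 = math.sqrt(2.0)


def grid_edges(values: np.ndarray, cell_size: float, neighbors: int = 8):
    """Adjacency list of the lattice graph with averaged-resistance weights."""
    rows, cols = values.shape
    offsets = [(0, 1, 1.0), (1, 0, 1.0), (0, -1, 1.0), (-1, 0, 1.0)]
    if neighbors == 8:
        offsets += [(1, 1, SQRT2), (1, -1, SQRT2), (-1, 1, SQRT2), (-1, -1, SQRT2)]
    adj: dict[tuple[int, int], list[tuple[tuple[int, int], float]]] = {}
    for r in range(rows):
        for c in range(cols):
            edges = []
            for dr, dc, dist in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    w = cell_size * dist * (values[r, c] + values[rr, cc]) / 2.0
                    edges.append(((rr, cc), w))
            adj[(r, c)] = edges
    return adj


def exhaustive_cost_field(
    values: np.ndarray, cell_size: float, source: tuple[int, int], neighbors: int = 8
) -> np.ndarray:
    """Least-cost field by depth-first enumeration of simple paths.

    Prunes a branch when its accumulated cost already reaches the best
    known cost of the node being entered; with strictly positive weights
    this cannot discard any optimal path, so the result is exact.
    """
    adj = grid_edges(values, cell_size, neighbors)
    best = {node: math.inf for node in adj}
    best[source] = 0.0
    stack = [(source, 0.0)]
    while stack:
        node, cost = stack.pop()
        if cost > best[node]:
            continue
        for nxt, w in adj[node]:
            nc = cost + w
            if nc < best[nxt]:
                best[nxt] = nc
                stack.append((nxt, nc))
    out = np.full(values.shape, math.inf)
    for (r, c), v in best.items():
        out[r, c] = v
    return out


def enumerate_all_simple_paths_cost(
    values: np.ndarray, cell_size: float, source: tuple[int, int], neighbors: int = 8
) -> np.ndarray:
    """Fully exhaustive minimum over ALL simple paths (no pruning).

    Exponential; only for tiny grids (<= 3x3).
    """
    adj = grid_edges(values, cell_size, neighbors)
    best = {node: math.inf for node in adj}
    best[source] = 0.0

    def dfs(node, cost, visited):
        for nxt, w in adj[node]:
            if nxt in visited:
                continue
            nc = cost + w
            if nc < best[nxt]:
                best[nxt] = nc
            dfs(nxt, nc, visited | {nxt})

    dfs(source, 0.0, {source})
    out = np.full(values.shape, math.inf)
    for (r, c), v in best.items():
        out[r, c] = v
    return out


def icc_bruteforce(matrix: np.ndarray) -> tuple[float, float]:
    """ICC(3,1)/ICC(3,k) from explicit definitional sums of squares.

    ``matrix``: complete experts (rows) x classes (columns) table.
    """
    x = np.asarray(matrix, dtype=float)
    k, n = x.shape
    grand = 0.0
    for i in range(k):
        for j in range(n):
            grand += x[i, j]
    grand /= k * n
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(k) for j in range(n))
    ss_class = sum(
        k * (sum(x[i, j] for i in range(k)) / k - grand) ** 2 for j in range(n)
    )
    ss_expert = sum(
        n * (sum(x[i, j] for j in range(n)) / n - grand) ** 2 for i in range(k)
    )
    ss_err = ss_total - ss_class - ss_expert
    ms_class = ss_class / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    single = (ms_class - ms_err) / (ms_class + (k - 1) * ms_err)
    average = (ms_class - ms_err) / ms_class
    return single, average


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta = (X'X)^-1 X'y, solved explicitly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def wright_fisher_mean_he(
    n_diploid: int,
    n_loci: int,
    n_alleles: int,
    generations: int,
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Neutral Wright-Fisher He trajectories.

    Returns an (n_reps, generations + 1) array of across-locus mean
    expected heterozygosity; generation 0 holds the founding sample drawn
    allele-by-allele from the uniform initial pool.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * n_diploid
    counts = rng.multinomial(
        two_n, np.full(n_alleles, 1.0 / n_alleles), size=(n_reps, n_loci)
    ).astype(float)
    out = np.empty((n_reps, generations + 1))

    def he(c):
        p = c / two_n
        return (1.0 - (p**2).sum(axis=2)).mean(axis=1)

    out[:, 0] = he(counts)
    for t in range(1, generations + 1):
        counts = rng.multinomial(two_n, counts / two_n).astype(float)
        out[:, t] = he(counts)
    return out


def crow_denniston_ne(n: float, kbar: float, vk: float) -> float:
    """Effective size from realized offspring-number mean and variance."""
    return (n * kbar - 2.0) / (kbar - 1.0 + vk / kbar)
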