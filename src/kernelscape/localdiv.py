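"""Local genetic-diversity surfaces with correlogram-derived windows.

Local (spatially windowed) diversity statistics require a neighbourhood
radius.  Following the sGD logic, the radius is taken from the spatial
scale of genetic autocorrelation: a Mantel correlogram is computed between
the pairwise genetic-distance matrix and equal-frequency cost-distance
classes; the window radius is half the range of the initial run of
significant positive autocorrelation.

Genetic distance is 1 minus the proportion of shared alleles (Dps),
counting the minimum multiplicity of each allele per locus — the metric
customarily paired with individual-based landscape-genetics simulations.

Sign convention: the per-class Mantel statistic reported here is
``r = -Pearson(genetic distance, within-class indicator)`` over the
off-diagonal pairs, so *positive* r means individuals within that
distance class are genetically more similar than average (positive
spatial genetic autocorrelation), as in the usual correlogram plots.
One-sided significance is assessed by jointly permuting rows and columns
of the genetic matrix.

Neighbourhoods are defined by least-cost (not Euclidean) distance by
default, honouring the landscape-genetics framing; pass a Euclidean
matrix to get the geometric variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Correlogram",
    "LocalDiversitySurface",
    "genetic_distances",
    "mantel_correlogram",
    "autocorrelation_range",
    "average_correlograms",
    "local_diversity",
]


@dataclass
class Correlogram:
    """Per-distance-class Mantel correlation.

    ``classes`` has columns lower, upper (cost units), mantel_r, p_value,
    n_pairs; classes are contiguous and ordered and cover all pairs.
    """

    classes: pd.DataFrame
    n_perm: int
    alpha: float


@dataclass
class LocalDiversitySurface:
    """Per-point local diversity; NaN where the window holds < min_n."""

    table: pd.DataFrame  # point, local_n, alleles_per_locus, ho, he
    window_radius: float
    min_n: int


def genetic_distances(genotypes: np.ndarray) -> np.ndarray:
    """Proportion-of-shared-alleles distance matrix (Dps).

    ``genotypes``: (n, n_loci, 2) allele identifiers.
    ``D(i, j) = 1 - shared / (2 L)`` where shared counts, per locus, the
    summed minimum multiplicity of each allele in the two genotypes.
    """
    g = np.asarray(genotypes)
    if g.ndim != 3 or g.shape[2] != 2:
        raise ValueError("genotypes must have shape (n, n_loci, 2)")
    n, L, _ = g.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    shared = np.zeros((n, n))
    for loc in range(L):
        alleles = np.unique(g[:, loc, :])
        # per-individual allele multiplicity vector (entries 0, 1 or 2)
        counts = (
            (g[:, loc, 0, None] == alleles[None, :]).astype(np.int16)
            + (g[:, loc, 1, None] == alleles[None, :]).astype(np.int16)
        )
        # sum_k min(c_i, c_j) = (|c_i| + |c_j| - |c_i - c_j|_1) / 2 = 2 - L1/2
        l1 = np.abs(counts[:, None, :] - counts[None, :, :]).sum(axis=2)
        shared += 2.0 - l1 / 2.0
    d = 1.0 - shared / (2.0 * L)
    np.fill_diagonal(d, 0.0)
    return d


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_correlogram(
    gen: np.ndarray,
    cost: np.ndarray,
    n_classes: int = 8,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> Correlogram:
    """Mantel correlogram over equal-frequency cost-distance classes.

    Permutation p-values are one-sided (large r); the same ``n_perm``
    row/column permutations of the genetic matrix are shared across
    classes.
    """
    gen = np.asarray(gen, dtype=float)
    cost = np.asarray(cost, dtype=float)
    if gen.shape != cost.shape or gen.shape[0] != gen.shape[1]:
        raise ValueError("matrices must be square and aligned")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    n = gen.shape[0]
    cost_u = _upper(cost)
    gen_u = _upper(gen)
    if np.allclose(gen_u, gen_u[0]) or np.allclose(cost_u, cost_u[0]):
        raise ValueError("degenerate (constant) distance matrix")

    qs = np.quantile(cost_u, np.linspace(0, 1, n_classes + 1))
    qs[0], qs[-1] = -np.inf, np.inf  # contiguous cover of all pairs
    membership = np.searchsorted(qs[1:-1], cost_u, side="left")

    indicators = np.stack(
        [(membership == c).astype(float) for c in range(n_classes)]
    )  # (n_classes, n_pairs)
    ind_c = indicators - indicators.mean(axis=1, keepdims=True)
    ind_ss = np.sqrt((ind_c**2).sum(axis=1))

    def class_r(g_u: np.ndarray) -> np.ndarray:
        gc = g_u - g_u.mean()
        g_ss = np.sqrt((gc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ind_c @ gc) / (ind_ss * g_ss)
        return -r  # positive r = similarity within class

    r_obs = class_r(gen_u)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    exceed = np.zeros(n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = gen[np.ix_(perm, perm)]
        exceed += class_r(gp[iu]) >= r_obs - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)

    lower = np.quantile(cost_u, np.linspace(0, 1, n_classes + 1))[:-1]
    upper = np.quantile(cost_u, np.linspace(0, 1, n_classes + 1))[1:]
    classes = pd.DataFrame(
        {
            "lower": lower,
            "upper": upper,
            "mantel_r": r_obs,
            "p_value": p,
            "n_pairs": indicators.sum(axis=1).astype(int),
        }
    )
    return Correlogram(classes, n_perm, alpha)


def autocorrelation_range(c: Correlogram, alpha: float | None = None) -> float:
    """Upper bound of the initial run of significant positive classes.

    Zero if the first class is already non-significant.
    """
    alpha = c.alpha if alpha is None else alpha
    rng_val = 0.0
    for _, row in c.classes.iterrows():
        if row["mantel_r"] > 0 and row["p_value"] < alpha:
            rng_val = float(row["upper"])
        else:
            break
    return rng_val


def average_correlograms(correlograms: list[Correlogram]) -> Correlogram:
    """Across-replicate combination: mean r per class, median p per class.

    All correlograms must share their class bounds (same cost matrix).
    """
    if not correlograms:
        raise ValueError("no correlograms to combine")
    ref = correlograms[0].classes
    for c in correlograms[1:]:
        if not np.allclose(c.classes["upper"], ref["upper"]):
            raise ValueError("correlogram class bounds differ")
    r = np.mean([c.classes["mantel_r"].to_numpy() for c in correlograms], axis=0)
    p = np.median([c.classes["p_value"].to_numpy() for c in correlograms], axis=0)
    out = ref.copy()
    out["mantel_r"] = r
    out["p_value"] = p
    return Correlogram(out, correlograms[0].n_perm, correlograms[0].alpha)


def local_diversity(
    genotypes: np.ndarray,
    individual_points: np.ndarray,
    cost_matrix: np.ndarray,
    radius: float,
    min_n: int = 10,
    points: np.ndarray | None = None,
) -> LocalDiversitySurface:
    """Windowed allelic richness and heterozygosity around each point.

    Parameters
    ----------
    genotypes
        (n_ind, n_loci, 2) array.
    individual_points
        (n_ind,) location index of each individual.
    cost_matrix
        (n_points, n_points) pairwise least-cost distances between
        locations.
    radius
        Window radius in cost units (inclusive; each point's own
        individual, if any, is always inside).
    min_n
        Minimum individuals for a non-missing estimate.
    points
        Location indices to evaluate (default: all rows of the matrix).
    """
    if not radius > 0:
        raise ValueError("radius must be > 0")
    if min_n < 2:
        raise ValueError("min_n must be >= 2")
    g = np.asarray(genotypes)
    ind_pts = np.asarray(individual_points)
    n_points = cost_matrix.shape[0]
    eval_points = np.arange(n_points) if points is None else np.asarray(points)

    L = g.shape[1]
    rows = []
    for p in eval_points:
        inside = cost_matrix[p, ind_pts] <= radius
        idx = np.flatnonzero(inside)
        ln = len(idx)
        if ln < min_n:
            rows.append((int(p), ln, np.nan, np.nan, np.nan))
            continue
        sub = g[idx]
        n_alleles = 0
        he_sum = 0.0
        for loc in range(L):
            alleles, counts = np.unique(sub[:, loc, :], return_counts=True)
            n_alleles += len(alleles)
            freq = counts / counts.sum()
            he_sum += 1.0 - float((freq**2).sum())
        ho = float((sub[:, :, 0] != sub[:, :, 1]).mean())
        rows.append((int(p), ln, n_alleles / L, ho, he_sum / L))
    table = pd.DataFrame(
        rows, columns=["point", "local_n", "alleles_per_locus", "ho", "he"]
    )
    return LocalDiversitySurface(table, radius, min_n)
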