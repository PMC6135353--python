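"""Individual-based, spatially explicit landscape-genetics simulation.

A fixed set of point locations (the disperser source points) acts as the
habitat: every location holds at most one diploid individual, so the point
count is the carrying capacity.  Generations are non-overlapping.  Each
generation:

1. every female draws a mate among males within the maximum cost-weighted
   dispersal distance, with probability proportional to an inverse-square
   function of the pairwise least-cost distance (males may mate repeatedly);
2. each mating produces a Poisson number of offspring; each offspring
   inherits one random allele per parent per locus (Mendelian);
3. every transmitted allele copy mutates with a fixed per-copy probability
   to a globally novel allele identifier (infinite-allele model, so allele
   counts can exceed the initial pool);
4. all adults die;
5. offspring, in random order, settle on vacant locations within the
   maximum dispersal distance of their natal (maternal) location, with
   probability proportional to the same inverse-square weight; an
   offspring with no reachable vacant location dies.

With ``maintain_capacity`` (the default, emulating the constant-capacity
regime of classic individual-based landscape-genetics simulators), every
location that remains vacant after settlement and is reachable from at
least one brood recruits one additional offspring, drawn from the
realized matings with probability proportional to the movement weight
from the natal location.  The population then sits at the carrying
capacity of *reachable* sites each generation — habitat fragmentation,
not demographic noise, drives population decline.  With the flag off,
per-capita replacement is exactly one (half the adults are female, each
brood has mean ``offspring_mean = 2``) and the population follows an
open critical branching walk.

Movement weights use a distance floor of one cell-length so that the
inverse square is finite at zero distance.  Realized mating and dispersal
cost-distances, and the realized per-parent offspring numbers (from which
an effective population size can be estimated), are recorded each
generation.

The global summary statistics follow the usual population-genetics
definitions: He = mean over loci of 1 - sum(p_k^2), Ho = fraction of
heterozygous individual-locus pairs, F = 1 - Ho/He (NaN-signalled when
He = 0), and the total allele count is summed over loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import pairwise_cost_matrix
from .resistance import ResistanceGrid, SourcePointSet

__all__ = [
    "SimParams",
    "PopulationState",
    "GeneticSummary",
    "init_population",
    "movement_weight",
    "step_generation",
    "run_replicates",
    "run_simulation",
    "global_genetic_summary",
    "inbreeding_coefficient",
    "summarize_replicates",
]


@dataclass
class SimParams:
    """Simulation parameters (defaults are the standard landscape-genetics
    configuration: 30 loci x 10 alleles, mu = 5e-4, Poisson(2) broods,
    inverse-square movement, 200 generations, 10 replicates)."""

    n_loci: int = 30
    n_init_alleles: int = 10
    mutation_rate: float = 0.0005
    offspring_mean: float = 2.0
    max_cost_distance: float = 125_000.0
    generations: int = 200
    n_reps: int = 10
    movement_exponent: float = 2.0
    cell_size: float = 1000.0  # metres; sets the distance floor of the weight
    maintain_capacity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not self.max_cost_distance > 0:
            raise ValueError("max_cost_distance must be > 0")


@dataclass
class PopulationState:
    """Individuals at point locations with diploid multilocus genotypes."""

    locations: np.ndarray  # (n,) indices into the location set
    sexes: np.ndarray  # (n,) bool, True = female
    genotypes: np.ndarray  # (n, n_loci, 2) allele identifiers
    generation: int
    n_locations: int
    next_allele: int  # next novel allele identifier for mutation

    def __post_init__(self) -> None:
        if len(np.unique(self.locations)) != len(self.locations):
            raise ValueError("a location may hold at most one individual")

    @property
    def n(self) -> int:
        return len(self.locations)

    @property
    def extinct(self) -> bool:
        return self.n == 0


@dataclass
class GeneticSummary:
    n: int
    he: float
    ho: float
    f: float  # NaN when He = 0 (undefined)
    total_alleles: int
    mean_mating_cost: float = math.nan
    mean_dispersal_cost: float = math.nan


def inbreeding_coefficient(he: float, ho: float) -> float:
    """F = 1 - Ho / He; NaN (undefined) when He = 0."""
    if he == 0:
        return math.nan
    return 1.0 - ho / he


def init_population(
    sources: SourcePointSet, params: SimParams, rng: np.random.Generator | None = None
) -> PopulationState:
    """One individual per source location; uniform alleles, Bernoulli sexes."""
    n = len(sources)
    if n < 2:
        raise ValueError("need at least 2 source locations")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    sexes = rng.random(n) < 0.5
    genotypes = rng.integers(
        0, params.n_init_alleles, size=(n, params.n_loci, 2), dtype=np.int64
    )
    return PopulationState(
        locations=np.arange(n, dtype=np.int64),
        sexes=sexes,
        genotypes=genotypes,
        generation=0,
        n_locations=n,
        next_allele=params.n_init_alleles,
    )


def movement_weight(cost, params: SimParams):
    """Inverse-power movement weight with a one-cell distance floor.

    ``w = 1 / max(cost, cell_size)^p`` for ``cost <= max_cost_distance``,
    else 0; weights are normalized over candidates at the point of use.
    """
    c = np.asarray(cost, dtype=float)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(c, params.cell_size) ** params.movement_exponent
    w = np.where(c <= params.max_cost_distance, w, 0.0)
    w = np.where(np.isfinite(c), w, 0.0)
    return float(w) if w.ndim == 0 else w


@dataclass
class GenerationEvents:
    """Realized per-generation bookkeeping."""

    mating_costs: np.ndarray
    dispersal_costs: np.ndarray
    offspring_kbar: float  # mean settled offspring per adult
    offspring_vk: float  # variance of settled offspring per adult


def step_generation(
    state: PopulationState,
    cost_matrix: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[PopulationState, GenerationEvents]:
    """Advance one non-overlapping generation (mate, breed, mutate, settle)."""
    empty_events = GenerationEvents(
        np.empty(0), np.empty(0), math.nan, math.nan
    )
    if state.extinct:
        return replace(state, generation=state.generation + 1), empty_events

    females = np.flatnonzero(state.sexes)
    males = np.flatnonzero(~state.sexes)
    if len(females) == 0 or len(males) == 0:
        out = PopulationState(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=bool),
            np.empty((0, params.n_loci, 2), dtype=np.int64),
            state.generation + 1,
            state.n_locations,
            state.next_allele,
        )
        return out, empty_events

    floc = state.locations[females]
    mloc = state.locations[males]
    # (n_females x n_males) movement weights from pairwise location costs
    w = movement_weight(cost_matrix[np.ix_(floc, mloc)], params)
    row_sums = w.sum(axis=1)

    mother_idx: list[int] = []
    father_idx: list[int] = []
    brood: list[int] = []
    mating_costs: list[float] = []
    for fi, f in enumerate(females):
        if row_sums[fi] <= 0:
            continue  # isolated female: no reachable mate
        probs = w[fi] / row_sums[fi]
        m = males[rng.choice(len(males), p=probs)]
        k = rng.poisson(params.offspring_mean)
        if k == 0:
            continue
        mother_idx.append(f)
        father_idx.append(m)
        brood.append(k)
        mating_costs.append(float(cost_matrix[state.locations[f], state.locations[m]]))

    if not brood:
        out = PopulationState(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=bool),
            np.empty((0, params.n_loci, 2), dtype=np.int64),
            state.generation + 1,
            state.n_locations,
            state.next_allele,
        )
        return out, empty_events

    mothers = np.repeat(np.asarray(mother_idx), brood)
    fathers = np.repeat(np.asarray(father_idx), brood)
    n_off = len(mothers)
    L = params.n_loci

    # Mendelian inheritance: one random allele copy per parent per locus
    pick_m = rng.integers(0, 2, size=(n_off, L))
    pick_f = rng.integers(0, 2, size=(n_off, L))
    gm = np.take_along_axis(
        state.genotypes[mothers], pick_m[:, :, None], axis=2
    )[:, :, 0]
    gf = np.take_along_axis(
        state.genotypes[fathers], pick_f[:, :, None], axis=2
    )[:, :, 0]
    geno = np.stack([gm, gf], axis=2)

    # infinite-allele mutation: each transmitted copy mutates to a novel id
    next_allele = state.next_allele
    if params.mutation_rate > 0:
        mut = rng.random(geno.shape) < params.mutation_rate
        n_mut = int(mut.sum())
        if n_mut:
            geno[mut] = np.arange(next_allele, next_allele + n_mut)
            next_allele += n_mut

    off_sex = rng.random(n_off) < 0.5
    natal = state.locations[mothers]

    # settlement: random order, first-come claims on vacant locations
    order = rng.permutation(n_off)
    vacant = np.ones(state.n_locations, dtype=bool)  # all adults are dead
    settled_loc = np.full(n_off, -1, dtype=np.int64)
    dispersal_costs = np.full(n_off, np.nan)
    for o in order:
        costs = cost_matrix[natal[o]]
        w_d = movement_weight(costs, params)
        w_d = np.where(vacant, w_d, 0.0)
        total = w_d.sum()
        if total <= 0:
            continue  # no reachable vacant site: offspring dies
        site = rng.choice(state.n_locations, p=w_d / total)
        vacant[site] = False
        settled_loc[o] = site
        dispersal_costs[o] = costs[site]

    if params.maintain_capacity and vacant.any():
        # vacant reachable sites recruit one extra offspring from nearby broods
        mating_natal = state.locations[np.asarray(mother_idx)]
        extra_geno, extra_sex, extra_loc, extra_cost = [], [], [], []
        extra_mothers, extra_fathers = [], []
        vac_sites = np.flatnonzero(vacant)
        for site in vac_sites[rng.permutation(len(vac_sites))]:
            w_site = movement_weight(cost_matrix[mating_natal, site], params)
            total = w_site.sum()
            if total <= 0:
                continue  # unreachable from every brood: stays vacant
            mi = rng.choice(len(mating_natal), p=w_site / total)
            mom, dad = mother_idx[mi], father_idx[mi]
            pm = rng.integers(0, 2, size=L)
            pf = rng.integers(0, 2, size=L)
            g = np.stack(
                [
                    state.genotypes[mom, np.arange(L), pm],
                    state.genotypes[dad, np.arange(L), pf],
                ],
                axis=1,
            )
            if params.mutation_rate > 0:
                m = rng.random(g.shape) < params.mutation_rate
                n_m = int(m.sum())
                if n_m:
                    g[m] = np.arange(next_allele, next_allele + n_m)
                    next_allele += n_m
            extra_geno.append(g)
            extra_sex.append(bool(rng.random() < 0.5))
            extra_loc.append(site)
            extra_cost.append(float(cost_matrix[mating_natal[mi], site]))
            extra_mothers.append(mom)
            extra_fathers.append(dad)
            vacant[site] = False
        if extra_loc:
            geno = np.concatenate([geno, np.stack(extra_geno)], axis=0)
            off_sex = np.concatenate([off_sex, np.asarray(extra_sex, dtype=bool)])
            settled_loc = np.concatenate(
                [settled_loc, np.asarray(extra_loc, dtype=np.int64)]
            )
            dispersal_costs = np.concatenate([dispersal_costs, np.asarray(extra_cost)])
            mothers = np.concatenate([mothers, np.asarray(extra_mothers)])
            fathers = np.concatenate([fathers, np.asarray(extra_fathers)])

    alive = settled_loc >= 0
    # per-adult settled-offspring counts (each survivor credits both parents)
    k_adult = np.zeros(state.n, dtype=float)
    np.add.at(k_adult, mothers[alive], 1.0)
    np.add.at(k_adult, fathers[alive], 1.0)
    events = GenerationEvents(
        mating_costs=np.asarray(mating_costs),
        dispersal_costs=dispersal_costs[alive],
        offspring_kbar=float(k_adult.mean()),
        offspring_vk=float(k_adult.var()),
    )
    out = PopulationState(
        locations=settled_loc[alive],
        sexes=off_sex[alive],
        genotypes=geno[alive],
        generation=state.generation + 1,
        n_locations=state.n_locations,
        next_allele=next_allele,
    )
    return out, events


def global_genetic_summary(state: PopulationState) -> GeneticSummary:
    """He, Ho, F and total allele count for the whole population."""
    if state.n < 1:
        raise ValueError("empty population has no genetic summary")
    g = state.genotypes
    n, L, _ = g.shape
    he_sum = 0.0
    total_alleles = 0
    for loc in range(L):
        alleles, counts = np.unique(g[:, loc, :], return_counts=True)
        p = counts / counts.sum()
        he_sum += 1.0 - float((p**2).sum())
        total_alleles += len(alleles)
    he = he_sum / L
    ho = float((g[:, :, 0] != g[:, :, 1]).mean())
    return GeneticSummary(
        n=n, he=he, ho=ho, f=inbreeding_coefficient(he, ho), total_alleles=total_alleles
    )


def _trajectory_row(state: PopulationState, events: GenerationEvents | None) -> dict:
    if state.extinct:
        row = {
            "generation": state.generation,
            "n": 0,
            "he": math.nan,
            "ho": math.nan,
            "f": math.nan,
            "total_alleles": 0,
        }
    else:
        s = global_genetic_summary(state)
        row = {
            "generation": state.generation,
            "n": s.n,
            "he": s.he,
            "ho": s.ho,
            "f": s.f,
            "total_alleles": s.total_alleles,
        }
    row["mean_mating_cost"] = (
        float(np.mean(events.mating_costs))
        if events is not None and len(events.mating_costs)
        else math.nan
    )
    row["mean_dispersal_cost"] = (
        float(np.mean(events.dispersal_costs))
        if events is not None and len(events.dispersal_costs)
        else math.nan
    )
    row["offspring_kbar"] = events.offspring_kbar if events is not None else math.nan
    row["offspring_vk"] = events.offspring_vk if events is not None else math.nan
    return row


def run_replicates(
    cost_matrix: np.ndarray,
    params: SimParams,
    record_every: int = 1,
) -> tuple[list[pd.DataFrame], list[PopulationState]]:
    """Run ``params.n_reps`` independent replicates on one cost matrix.

    Returns per-replicate trajectory tables (one row per recorded
    generation) and the final population states.
    """
    cost_matrix = np.asarray(cost_matrix, dtype=float)
    if cost_matrix.shape[0] != cost_matrix.shape[1]:
        raise ValueError("cost matrix must be square")
    n_loc = cost_matrix.shape[0]

    class _FakeSources:
        def __len__(self) -> int:
            return n_loc

    trajectories: list[pd.DataFrame] = []
    finals: list[PopulationState] = []
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_reps)
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        state = init_population(_FakeSources(), params, rng)  # type: ignore[arg-type]
        rows = [_trajectory_row(state, None)]
        for _ in range(params.generations):
            state, events = step_generation(state, cost_matrix, params, rng)
            if (
                state.generation % record_every == 0
                or state.generation == params.generations
                or state.extinct
            ):
                rows.append(_trajectory_row(state, events))
            if state.extinct:
                break
        df = pd.DataFrame(rows)
        df.insert(0, "rep", rep)
        trajectories.append(df)
        finals.append(state)
    return trajectories, finals


def run_simulation(
    sources: SourcePointSet,
    resistance: ResistanceGrid,
    params: SimParams,
    record_every: int = 10,
) -> tuple[list[pd.DataFrame], list[PopulationState], np.ndarray]:
    """Build the pairwise least-cost matrix once, then run all replicates."""
    cost = pairwise_cost_matrix(resistance, sources)
    trajectories, finals = run_replicates(cost, params, record_every)
    return trajectories, finals, cost


def summarize_replicates(trajectories: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-replicate mean and sd of the final recorded generation."""
    finals = pd.concat([t.iloc[[-1]] for t in trajectories], ignore_index=True)
    cols = [
        "n",
        "he",
        "ho",
        "f",
        "total_alleles",
        "mean_mating_cost",
        "mean_dispersal_cost",
    ]
    out = pd.DataFrame(
        {"mean": finals[cols].mean(), "sd": finals[cols].std(ddof=1)}
    )
    out.index.name = "statistic"
    return out
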