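# Methods

This note documents the models, parameter choices and numerical
conventions behind `kernelscape`, and what the packaged synthetic system
does and does not emulate.

## Expert aggregation

Ratings are integers on a 1–5 interval scale; the per-class score is the
mean over responding experts and the reported spread is the population
(divide-by-*n*) standard deviation, the form consistent with summarising
a complete small panel rather than inferring a super-population.
Agreement uses the Shrout–Fleiss two-way mixed, consistency-form
intraclass correlations, with land-cover classes as the rated targets:

    ICC(3,1) = (MS_C − MS_E) / (MS_C + (k − 1)·MS_E)
    ICC(3,k) = (MS_C − MS_E) / MS_C

where MS_C is the between-class mean square, MS_E the residual mean
square and *k* the number of raters. Experts may skip classes, so two
missingness policies exist: `complete_case` (drop experts with any
missing class; the balanced ANOVA above) and `pairwise` (an unbalanced
additive class + expert least-squares fit, with *k* replaced by the mean
raters per class — an approximation, clearly flagged). The convenience
report defaults to `auto`: complete-case when at least two complete
raters exist, else the unbalanced fit, because realistic panels (e.g. 22 %
missingness over 7 classes) frequently have no complete rater at all.
Zero between-class variance makes the ICC undefined and is raised as an
error, never silently returned as 0.

## Resistance and source points

Resistance is a linear inversion of suitability onto [1, 100]. The
endpoints (s_min, s_max) are the *observed* extremes of the class means,
not the theoretical 1–5 scale, so the best rated class gets resistance
exactly 1 and the worst exactly 100 on the map. Bilinear resampling to a
coarser analysis cell samples the source field at the coarse-cell
centres; values are clipped back into [1, 100] afterwards.

The future-epoch projection defaults to the literal additive update
`min(100, r + risk·r_transition)`; an expectation form
`r + risk·(r_transition − r)` — the pointwise mean of the Bernoulli
conversion process — is available behind a flag. Both leave
zero-risk cells untouched.

Source seeding draws one Uniform(0,1) number per cell, weights it by
1/r, and keeps the top *n* cells; ties at the threshold order statistic
break by row-major cell index so the set is exactly reproducible.
Re-application to a later epoch reuses the *same* random grid (same
seed) and keeps cells with weight ≥ threshold; the inclusive comparison
makes re-application to the reference epoch the identity. A consequence
worth knowing: a selected cell sits essentially at `u ≈ threshold · r`,
so *any* resistance increase ejects it — later epochs retain points only
where resistance is exactly unchanged (in particular, where projected
risk is exactly zero).

## Connectivity engine

Costs accumulate over the 8-neighbour lattice (4-neighbour available)
with the standard GIS edge weight: centre-to-centre distance times the
mean of the two cells' resistances, ×√2 for diagonals. Shortest paths
come from Dijkstra on the sparse lattice graph (scipy); path extraction
follows the predecessor tree, which makes tie-breaking among equal-cost
paths deterministic for a fixed graph construction order — the property
the pipeline needs for reproducibility; no claim is made about *which*
of several equal-cost paths is returned. One path is extracted per
unordered source pair; pairs farther apart than the optional cost ceiling
contribute nothing.

The resistant kernel is linear with finite support,
`max(0, 1 − c/bandwidth)`, because the bandwidth is defined as the
species' maximum dispersal cost (125 kcu ≙ 125 km through ideal
habitat): the expected disperser density must reach zero exactly there.
Kernels from sources sharing a cell add.

The focal mean uses a circular window (cell centres within the radius,
inclusive) and averages the in-bounds part at edges, excluding nodata
cells from every window.

## Pattern metrics

Binary habitat maps cut each connectivity surface at a percentile of the
*reference* (first-epoch) surface, so all epochs face one absolute
threshold. The percentile is the linear-interpolation quantile and is
taken over positive reference values by default — kernel surfaces are
mostly zeros, and a low percentile over all cells would collapse to 0;
the all-cells variant is exposed for sensitivity work. Patches are
8-connected components (FRAGSTATS convention). Radius of gyration is the
mean distance from patch-cell centres to the patch centroid, and
correlation length its area-weighted mean over patches; an empty map has
all metrics 0 by definition.

## Individual-based genetic simulation

Sites are the source points; each holds at most one diploid individual,
so the point count is the carrying capacity. Generations do not overlap.
Movement (mating and natal dispersal) uses an inverse-square weight
`1/max(c, cell_size)²`, truncated beyond the maximum dispersal cost; the
one-cell floor keeps the weight finite at zero distance. Each female
draws one mate among reachable males (males may mate repeatedly), broods
are Poisson(2), inheritance is Mendelian, and every transmitted allele
copy mutates with probability 5·10⁻⁴ to a globally novel identifier
(infinite-allele model — allele counts can exceed the initial
30 × 10 pool). Offspring settle in random order on vacant sites
reachable from the natal (maternal) site.

Two demographic regimes are provided. The default, `maintain_capacity`,
emulates classic constant-capacity simulators: after settlement, every
still-vacant site reachable from at least one realized brood recruits
one extra offspring (parents chosen ∝ movement weight from the natal
site). Population size then equals the carrying capacity of *reachable*
sites each generation, and decline is driven by fragmentation, not
demographic noise. With the flag off, the model follows the literal
birth–death rules alone; per-capita replacement is then exactly one
(half the adults are female × mean brood 2), an open critical branching
walk that drifts or goes extinct within a few hundred generations at
the population sizes used here — useful for studying demographic
stochasticity, but not a regime in which 200-generation equilibria
exist.

Summaries follow the usual definitions: He = mean over loci of 1 − Σp²,
Ho = fraction of heterozygous individual–locus pairs, F = 1 − Ho/He
(NaN-signalled when He = 0), allele count summed over loci. Realized
mating and dispersal cost-distances and realized per-parent offspring
numbers are recorded each generation; the latter support an empirical
effective-size estimate (Crow–Denniston
`Ne = (N·k̄ − 2)/(k̄ − 1 + Vk/k̄)`), which the test suite uses to check
the He decay against a neutral Wright–Fisher oracle. With separate
sexes, heterozygosity reflects the parental generation's allele
frequencies, so the oracle comparison lags one generation.

## Local diversity and regression

Genetic distance is 1 − proportion of shared alleles (Dps), counting
minimum per-locus multiplicity. The Mantel correlogram bins pairwise
cost distances into equal-frequency classes; the reported statistic is
−Pearson(genetic distance, within-class indicator) over off-diagonal
pairs, so positive values mean genetic similarity within the class
(the usual correlogram orientation). Significance is one-sided by
row/column permutation of the genetic matrix, with the same permutations
shared across classes; across simulation replicates, correlograms are
combined as mean r and median p per class. The neighbourhood radius is
half the range of the initial run of significant positive classes;
when no class is significant the radius falls back to half the dispersal
ceiling. Neighbourhoods are cost-distance balls (Euclidean available by
passing a Euclidean matrix); local statistics require at least `min_n`
(default 10) individuals, else the point is reported missing.

Diversity–connectivity models are ordinary least squares; for Gaussian
least squares the deviance explained equals R², which makes the
single-predictor vs global comparison well defined. The kernel
predictor enters as `1/(kernel + ε)` with ε the smallest positive kernel
value, a data-driven guard against zero cells that linearizes the
strongly curvilinear kernel–diversity relationship. LOWESS curves
(span 2/3) are emitted as data for plotting.

## The packaged synthetic system

The demo scenario is a 120 × 120 grid of 1 km cells — a 120 km island
analogue. The paper-scale system it is modelled after spans ~1000 km
with dispersal ceilings of 125 and 250 kcu; the scenario keeps those
ratios with kernel bandwidths of 15 and 30 kcu and a 30 kcu simulation
dispersal ceiling, and uses 150 source points, 200 generations and 5
replicates so the full chain runs in well under a minute.

Land cover is made by thresholding Gaussian-smoothed white noise
(smoothing length 12 cells) at class-fraction quantiles; class insertion
order controls adjacency, placing the three forest classes (65 % of the
landscape) in a few large massifs fringed by mosaic and plantation
classes. Epoch-1 loss is modest and edge-concentrated (edge weight 0.5,
base rate 0.02): clearing trims massif margins. Epoch-2 risk is strongly
edge-driven (edge weight 1.0, base 0, e-folding 2 cells) with two
realism features: the edge distance is measured to the cleared
*frontier* (non-forest specks below a 2×2 opening are ignored — single
canopy gaps do not attract clearing fronts), and probabilities below
0.05 truncate to exactly zero, the sparse-risk structure fitted risk
models produce for remote interior forest. The zeros matter
structurally: only zero-risk cells can retain source points under the
threshold re-application (see above), exactly as a fitted risk map with
large zero-risk interiors retains most of its points.

What the generator does **not** emulate: real deforestation covariates
(roads, slope, tenure), topography, multi-date class transitions other
than forest → plantations/regrowth, spatially correlated expert error,
and any calibration of absolute density. Passing tests therefore show
that the *chain* behaves correctly under the assumed statistical
structure, not that the parameter values are right for any real
landscape.

A scale caveat for the genetics: with ~150 sites instead of thousands,
local genetic neighbourhoods hold tens rather than hundreds of
individuals, so baseline inbreeding is much higher and observed
heterozygosity much lower than in a full-scale system, and the pooled
(Wahlund-inflated) He responds less cleanly to fragmentation. The
directions of change across epochs — shrinking populations, falling
diversity, rising F, accelerating declines — are the reproducible
content at this scale; the levels are not comparable to large systems.

## Numerical conventions

- Rasters: top-left origin, row-major, 0-based; cell (r, c) centre at
  (x₀ + (c + ½)·Δ, y₀ − (r + ½)·Δ). Alignment mismatches raise; nothing
  resamples silently.
- Quantiles/percentiles: linear interpolation between order statistics.
- Ties: threshold order statistic by row-major index; equal-cost paths
  by the shortest-path tree's deterministic construction order.
- Seeds: every stochastic stage takes an explicit integer seed; the
  pipeline splits its master seed into named per-stage substreams
  (stable hash of the stage name) so stages can be rerun in isolation.
- Degenerate inputs signal: empty rating sets, zero between-class
  variance, constant distance matrices, He = 0 (F undefined), empty
  reference surfaces all raise or return NaN explicitly, never 0.
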