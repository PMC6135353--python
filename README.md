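# kernelscape

Landscape connectivity and landscape genetics for a forest carnivore under
rapid deforestation.

`kernelscape` implements, as one reusable and tested pipeline, the full
analysis chain that links expert habitat opinion to projected population
size, connectivity and genetic diversity across a changing landscape:

1. **Expert elicitation** — a panel rates the habitat suitability of each
   land-cover class on a 1–5 interval scale; per-class means are the
   suitability scores, agreement is quantified with the two-way mixed,
   consistency-form intraclass correlation (ICC(3,1) single rater,
   ICC(3,k) panel average), and the panel's density estimates are
   regressed on suitability as an internal-coherence check.
2. **Resistance mapping** — suitability *s* is inverted and rescaled to
   movement resistance `r = 1 + 99·(s_max − s)/(s_max − s_min)` ∈ [1, 100]
   (1 = ideal habitat), rasterised per class and resampled bilinearly to
   the analysis cell size. A future epoch with unknown land cover is
   projected from a deforestation-risk surface:
   `r_future = min(100, r_now + risk · r_transition)`, where
   `r_transition` is the resistance of the plantations/regrowth class.
3. **Source points** — dispersers are seeded proportionally to habitat
   quality: an i.i.d. Uniform(0,1) grid is divided by resistance and the
   top *n* cells are kept; re-applying the implied threshold (same random
   grid) to later epochs yields shrinking point sets as resistance rises.
4. **Connectivity** — movement cost accumulates over the 8-neighbour
   lattice with edge weight `cell_size · (r_a + r_b)/2` (×√2 diagonally),
   so one cost unit (cu) is one metre through resistance-1 habitat.
   Two synoptic surfaces are built from multi-source Dijkstra trees:
   the **cumulative resistant kernel** `Σ_i max(0, 1 − c_i/bandwidth)`
   (expected disperser density, finite support at the dispersal limit),
   and **factorial least-cost-path density** (one least-cost path per
   source pair, each cell on it counts 1), smoothed by a circular focal
   mean.
5. **Pattern metrics** — kernel and path-density surfaces are thresholded
   at a percentile of the first epoch's surface, and the binary habitat
   maps are summarised by PLAND, largest patch index, patch count and
   correlation length (area-weighted mean radius of gyration), with
   relative changes between epochs.
6. **Individual-based genetics** — diploid individuals occupy the source
   points (one per site); each generation females choose mates and
   offspring settle on vacant sites with probability ∝ 1/cost², truncated
   at the maximum dispersal cost; 30 loci × 10 alleles, infinite-allele
   mutation at 5·10⁻⁴, Poisson(2) broods, non-overlapping generations.
   He, Ho, F = 1 − Ho/He and the total allele count are tracked for 200
   generations over replicate runs.
7. **Local diversity and regression** — a Mantel correlogram against
   cost-distance classes sets the radius of local genetic neighbourhoods;
   windowed allelic richness and heterozygosity are then regressed on
   focal-mean resistance, path density and (reciprocal) kernel density to
   ask which cheap surface best predicts simulated diversity.

Everything runs on synthetic rasters generated by the package itself — a
three-date land-cover series with edge-concentrated forest loss, a
deforestation-risk surface and a noisy expert panel — so the whole chain
is testable end-to-end with no external data.

## Worked example

Run the packaged three-epoch scenario (120×120 km at 1 km cells,
150 source points, kernels at 15 and 30 kcu, 200 generations × 5
replicates) from the command line:

```bash
kernelscape run-all --config demo.yaml     # or use the library directly
```

```python
from kernelscape import ScenarioConfig, run_scenario
manifest = run_scenario(ScenarioConfig(out_dir="demo_out", seed=1))
print(manifest["source_point_counts"])
```

At seed 1 this prints `{'t0': 150, 't1': 139, 't2': 65}`: the seeding
threshold that gives 150 points on the first epoch keeps only 139 on the
second and 65 on the risk-projected third, because rising resistance
pushes cells below the threshold. The output directory then contains the
resistance, kernel and path-density rasters, pattern metrics and
simulation tables. Headline numbers from that run:

| quantity | t0→t1 | t1→t2 |
|---|---|---|
| connected area (PLAND, 30 kcu kernel, 10th pctl) | −12.1 % | −62.2 % |
| simulated population at generation 200 | −7.9 % | −65.6 % |
| inbreeding coefficient F at generation 200 | 0.67 → 0.71 | 0.71 → 0.94 |

The second interval's declines far exceed the first's — the fingerprint
of edge-driven forest loss accelerating once clearing fronts penetrate
the remaining massifs — while expected heterozygosity and allele counts
fall and inbreeding rises as the surviving habitat fragments. The
synthetic expert panel aggregates with ICC(3,k) = 0.96 and a
suitability–density R² of 0.98, i.e. the high-agreement regime the
elicitation design assumes.

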