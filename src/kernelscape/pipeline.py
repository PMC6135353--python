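"""Three-epoch scenario orchestration.

``run_scenario`` executes the whole chain from a single config: expert
aggregation -> resistance maps for the three dates (the last projected
from the deforestation-risk surface) -> source-point seeding and
threshold re-application -> cumulative resistant kernels and factorial
least-cost-path density -> binary habitat maps and pattern metrics with
between-interval relative changes -> individual-based genetic simulation
per epoch -> local genetic-diversity surfaces -> diversity-vs-
connectivity regressions.  Every intermediate raster/table is written to
the output directory and listed, with a SHA-256 hash, in a manifest; a
rerun with the same config reproduces all outputs bit-identically.

Seeding: the master seed is split into named per-stage substreams
(stable hash of the stage name), so stages can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import landcover as lc
from . import localdiv, metrics, regress, simulate
from .experts import ExpertRatingSet, agreement_report, aggregate_ratings
from .raster import read_raster, write_raster
from .resistance import (
    build_resistance,
    project_future_resistance,
    reapply_threshold,
    seed_source_points,
    suitability_to_resistance,
)

__all__ = ["ScenarioConfig", "run_scenario"]


@dataclass
class ScenarioConfig:
    """Everything needed to run one three-epoch scenario.

    With no explicit raster paths the packaged synthetic scenario is
    generated at ``shape``/``cell_size``.  Bandwidths and the simulation
    dispersal limit are in cost units; defaults keep the
    bandwidth-to-extent ratio of a large island study on the packaged
    120 km fixture.
    """

    out_dir: str = "scenario_out"
    seed: int = 1
    shape: tuple[int, int] = (120, 120)
    cell_size: float = 1000.0
    n_source_points: int = 150
    bandwidths: tuple[float, ...] = (15_000.0, 30_000.0)
    percentiles: tuple[float, ...] = (10.0, 5.0, 20.0)
    sim_bandwidth: float = 30_000.0
    generations: int = 200
    n_reps: int = 5
    n_loci: int = 30
    mutation_rate: float = 0.0005
    focal_radius: float = 10_000.0
    correlogram_classes: int = 8
    correlogram_permutations: int = 199
    min_local_n: int = 10
    landcover_paths: tuple[str, ...] | None = None  # optional t0,t1 rasters
    risk_path: str | None = None
    ratings_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("shape", "bandwidths", "percentiles"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                setattr(cfg, name, tuple(val))
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _stage_seed(master: int, stage: str) -> int:
    return (master * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_scenario(config: ScenarioConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the output manifest."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    files: list[str] = []

    def save_raster(grid, name: str) -> None:
        path = os.path.join(out, name)
        write_raster(grid, path)
        files.append(name)

    def save_df(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(os.path.join(out, name), **kw)
        files.append(name)

    # -- stage: synthetic scenario (or load user rasters) -------------------
    if config.landcover_paths:
        raise NotImplementedError(
            "external land-cover input requires a class table; use the CLI "
            "resistance subcommand for file-based runs"
        )
    scen = lc.make_demo_scenario(
        _stage_seed(config.seed, "synth"), config.shape, config.cell_size
    )
    epochs = [g.epoch_label for g in scen.grids]
    for g in scen.grids:
        save_raster(g.raster, f"landcover_{g.epoch_label}.tif")
    save_raster(scen.risk, "deforestation_risk.tif")
    scen.panel.to_csv(os.path.join(out, "expert_ratings.csv"))
    files.append("expert_ratings.csv")

    # -- stage: expert aggregation ------------------------------------------
    panel = (
        ExpertRatingSet.from_csv(config.ratings_path)
        if config.ratings_path
        else scen.panel
    )
    table = aggregate_ratings(panel)
    table.to_csv(os.path.join(out, "suitability_table.csv"))
    files.append("suitability_table.csv")
    agreement = agreement_report(panel)
    agreement.to_csv(os.path.join(out, "agreement_report.csv"))
    files.append("agreement_report.csv")

    # -- stage: resistance maps ---------------------------------------------
    r_t0 = build_resistance(scen.grids[0], table)
    r_t1 = build_resistance(scen.grids[1], table)
    r_transition = suitability_to_resistance(
        table.mean_suitability(scen.grids[0].classes.transition_target),
        table.s_min,
        table.s_max,
    )
    r_t2 = project_future_resistance(r_t1, scen.risk, r_transition, epoch_label="t2")
    resist = {"t0": r_t0, "t1": r_t1, "t2": r_t2}
    for label, r in resist.items():
        save_raster(r.raster, f"resistance_{label}.tif")

    # -- stage: source points -----------------------------------------------
    seed_pts = _stage_seed(config.seed, "sources")
    sources = {"t0": seed_source_points(r_t0, config.n_source_points, seed_pts)}
    for label in ("t1", "t2"):
        sources[label] = reapply_threshold(
            resist[label], sources["t0"].threshold, seed_pts
        )
    for label, sp in sources.items():
        sp.to_csv(os.path.join(out, f"source_points_{label}.csv"))
        files.extend([f"source_points_{label}.csv", f"source_points_{label}.csv.meta.json"])

    # -- stage: connectivity surfaces ---------------------------------------
    kernels: dict[tuple[str, float], conn.KernelSurface] = {}
    for label, r in resist.items():
        for bw in config.bandwidths:
            if len(sources[label]) > 0:
                k = conn.cumulative_resistant_kernel(r, sources[label], bw)
            else:  # no sources left: zero expected disperser density
                k = conn.KernelSurface(
                    r.raster.copy(np.zeros(r.raster.shape)), bw, label
                )
            kernels[(label, bw)] = k
            save_raster(k.raster, f"kernel_{label}_{int(bw // 1000)}kcu.tif")
    lcps: dict[str, conn.PathDensitySurface] = {}
    lcps_smooth: dict[str, conn.PathDensitySurface] = {}
    for label, r in resist.items():
        if len(sources[label]) >= 2:
            p = conn.factorial_least_cost_paths(r, sources[label])
        else:  # a fully disconnected epoch has an empty path network
            p = conn.PathDensitySurface(
                r.raster.copy(np.zeros(r.raster.shape, dtype=np.int64)), False, 0.0, label
            )
        lcps[label] = p
        sm_r = conn.focal_mean(p.raster.copy(p.raster.values.astype(float)), config.focal_radius)
        lcps_smooth[label] = conn.PathDensitySurface(sm_r, True, config.focal_radius, label)
        save_raster(p.raster, f"LCP_{label}.tif")
        save_raster(sm_r, f"LCP_{label}_smoothed.tif")

    # -- stage: pattern metrics ---------------------------------------------
    n_cells = int(np.prod(config.shape))
    rows = []
    for pct in config.percentiles:
        for bw in config.bandwidths:
            ref = kernels[(epochs[0], bw)].raster
            for label in epochs:
                b = metrics.threshold_to_binary(
                    kernels[(label, bw)].raster, ref, pct, reference_epoch=epochs[0]
                )
                rep = metrics.compute_metrics(metrics.label_patches(b), n_cells)
                rows.append(
                    {"surface": "kernel", "epoch": label, "bandwidth": bw,
                     "percentile": pct, **rep.as_dict()}
                )
        ref = lcps_smooth[epochs[0]].raster
        for label in epochs:
            b = metrics.threshold_to_binary(
                lcps_smooth[label].raster, ref, pct, reference_epoch=epochs[0]
            )
            rep = metrics.compute_metrics(metrics.label_patches(b), n_cells)
            rows.append(
                {"surface": "lcp", "epoch": label, "bandwidth": np.nan,
                 "percentile": pct, **rep.as_dict()}
            )
    metrics_df = pd.DataFrame(rows)
    save_df(metrics_df, "metrics.csv", index=False)

    change_rows = []
    for (surface, bw, pct), grp in metrics_df.groupby(
        ["surface", "bandwidth", "percentile"], dropna=False, sort=False
    ):
        grp = grp.set_index("epoch")
        for col in ("pland", "lpi", "n_patches", "correlation_length"):
            try:
                c1 = metrics.relative_change(
                    grp.loc[epochs[0], col], grp.loc[epochs[1], col]
                )
                c2 = metrics.relative_change(
                    grp.loc[epochs[1], col], grp.loc[epochs[2], col]
                )
            except ValueError:
                c1 = c2 = np.nan
            change_rows.append(
                {"surface": surface, "bandwidth": bw, "percentile": pct,
                 "metric": col, "change_interval1_pct": c1, "change_interval2_pct": c2}
            )
    save_df(pd.DataFrame(change_rows), "metric_changes.csv", index=False)

    # -- stage: genetic simulation ------------------------------------------
    sim_summaries = {}
    sim_results = {}
    for label in epochs:
        params = simulate.SimParams(
            n_loci=config.n_loci,
            mutation_rate=config.mutation_rate,
            max_cost_distance=config.sim_bandwidth,
            generations=config.generations,
            n_reps=config.n_reps,
            cell_size=config.cell_size,
            seed=_stage_seed(config.seed, f"sim_{label}"),
        )
        if len(sources[label]) < 2:
            # no viable population: record an extinct-from-the-start epoch
            empty = pd.DataFrame(
                [{"rep": 0, "generation": 0, "n": 0, "he": np.nan, "ho": np.nan,
                  "f": np.nan, "total_alleles": 0, "mean_mating_cost": np.nan,
                  "mean_dispersal_cost": np.nan, "offspring_kbar": np.nan,
                  "offspring_vk": np.nan}]
            )
            traj, finals, cost = [empty], [], np.zeros((0, 0))
        else:
            traj, finals, cost = simulate.run_simulation(
                sources[label], resist[label], params
            )
        sim_results[label] = (traj, finals, cost, params)
        all_traj = pd.concat(traj, ignore_index=True)
        save_df(all_traj, f"sim_trajectories_{label}.csv", index=False)
        summ = simulate.summarize_replicates(traj)
        sim_summaries[label] = summ
        save_df(summ, f"sim_summary_{label}.csv")

    # -- stage: local genetic diversity + regression -------------------------
    regression_rows = []
    for label in epochs:
        traj, finals, cost, params = sim_results[label]
        live = [s for s in finals if not s.extinct and s.n >= 3]
        if not live:
            continue
        correlograms = []
        for s in live:
            gen_d = localdiv.genetic_distances(s.genotypes)
            sub_cost = cost[np.ix_(s.locations, s.locations)]
            finite = np.isfinite(sub_cost)
            sub_cost = np.where(finite, sub_cost, np.nanmax(sub_cost[finite]) * 2)
            try:
                correlograms.append(
                    localdiv.mantel_correlogram(
                        gen_d,
                        sub_cost,
                        n_classes=config.correlogram_classes,
                        n_perm=config.correlogram_permutations,
                        seed=_stage_seed(config.seed, f"mantel_{label}"),
                    )
                )
            except ValueError:
                continue
        radius = config.sim_bandwidth / 2.0
        if correlograms:
            try:
                avg = localdiv.average_correlograms(correlograms)
                rng_sig = localdiv.autocorrelation_range(avg)
                if rng_sig > 0:
                    radius = rng_sig / 2.0
            except ValueError:
                pass
        # pool individuals across replicate final states for the local surface
        cost_finite = np.where(np.isfinite(cost), cost, np.inf)
        div_tables = []
        for rep_i, s in enumerate(live):
            surf = localdiv.local_diversity(
                s.genotypes, s.locations, cost_finite, radius, config.min_local_n
            )
            t = surf.table
            t.insert(0, "rep", rep_i)
            div_tables.append(t)
        div_all = pd.concat(div_tables, ignore_index=True)
        save_df(div_all, f"local_diversity_{label}.csv", index=False)

        # regression on the across-rep mean local diversity per point
        div_mean = (
            div_all.dropna(subset=["alleles_per_locus", "ho"])
            .groupby("point", as_index=False)[["local_n", "alleles_per_locus", "ho", "he"]]
            .mean()
        )
        surface = localdiv.LocalDiversitySurface(div_mean, radius, config.min_local_n)
        try:
            ptable = regress.assemble_predictor_table(
                sources[label],
                resist[label],
                kernels[(label, config.sim_bandwidth)]
                if (label, config.sim_bandwidth) in kernels
                else kernels[(label, config.bandwidths[0])],
                lcps_smooth[label],
                surface,
                config.focal_radius,
            )
            for response in ("alleles", "ho"):
                comp = regress.fit_diversity_models(ptable, response=response)
                for _, mrow in comp.models.iterrows():
                    regression_rows.append(
                        {"epoch": label, "response": response,
                         "model": mrow["model"],
                         "deviance_explained": mrow["deviance_explained"]}
                    )
        except ValueError:
            pass
    if regression_rows:
        save_df(pd.DataFrame(regression_rows), "regression_models.csv", index=False)

    # -- manifest -------------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "seeds": {
            stage: _stage_seed(config.seed, stage)
            for stage in ["synth", "sources"]
            + [f"sim_{e}" for e in epochs]
            + [f"mantel_{e}" for e in epochs]
        },
        "source_point_counts": {k: len(v) for k, v in sources.items()},
        "files": {name: _sha256(os.path.join(out, name)) for name in sorted(set(files))},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
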