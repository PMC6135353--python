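"""Suitability-to-resistance translation and disperser source seeding.

Habitat suitability (1-5 panel means) is inverted and linearly rescaled to
landscape resistance in [1, 100]: resistance 1 in the best observed
habitat class and 100 in the worst.  The (s_min, s_max) endpoints are the
*observed* class means, so both endpoints are attained on the map.  The
per-class resistance surface is then resampled to the analysis cell size
with bilinear interpolation (coarse cells make the all-pairs connectivity
stage tractable and have little effect on predicted gene flow).

A future epoch whose land cover is unknown is projected from a
deforestation-risk surface: the risk is multiplied by the resistance the
cell would have as the transition class (plantations/regrowth analogue)
and the product added to the current resistance ("literal" mode, capped at
100).  An expectation-form update r + risk * (r_transition - r), which is
the probabilistic mean of the cell's future resistance, is available via
``mode="expectation"``.

Source points for dispersers are seeded proportionally to habitat quality:
an i.i.d. Uniform(0,1) grid is divided by resistance and the top
``n_target`` cells selected; the implied threshold can then be re-applied
(with the *same* random grid) to later epochs, so the point count falls as
resistance rises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .experts import SuitabilityTable
from .landcover import LandCoverGrid
from .raster import RasterGrid, check_aligned

__all__ = [
    "ResistanceGrid",
    "SourcePointSet",
    "suitability_to_resistance",
    "resistance_to_suitability",
    "build_resistance",
    "project_future_resistance",
    "seed_source_points",
    "reapply_threshold",
]


@dataclass
class ResistanceGrid:
    """Resistance raster with values in [1, 100]; 1 = ideal habitat."""

    raster: RasterGrid
    epoch_label: str = ""

    def __post_init__(self) -> None:
        v = self.raster.values[self.raster.data_mask()]
        if v.size and (v.min() < 1.0 - 1e-9 or v.max() > 100.0 + 1e-9):
            raise ValueError(
                f"resistance values must lie in [1, 100], got [{v.min()}, {v.max()}]"
            )


@dataclass
class SourcePointSet:
    """Seeded disperser locations with the threshold that produced them."""

    points: np.ndarray  # (n, 2) int array of (row, col)
    threshold: float
    seed: int
    epoch_label: str = ""
    n_target: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)
        if len(np.unique(self.points, axis=0)) != len(self.points):
            raise ValueError("source points must be unique")

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.points, columns=["row", "col"]).to_csv(path, index=False)
        meta = {
            "threshold": self.threshold,
            "seed": self.seed,
            "epoch_label": self.epoch_label,
            "n_target": self.n_target,
        }
        with open(path + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str) -> "SourcePointSet":
        pts = pd.read_csv(path)[["row", "col"]].to_numpy()
        with open(path + ".meta.json") as fh:
            meta = json.load(fh)
        return cls(pts, meta["threshold"], meta["seed"], meta["epoch_label"], meta["n_target"])


def suitability_to_resistance(s, s_min: float, s_max: float):
    """Invert and rescale suitability to resistance in [1, 100].

    ``r = 1 + 99 (s_max - s) / (s_max - s_min)``; monotone decreasing, with
    the endpoints mapping to exactly 100 and 1.
    """
    if not s_min < s_max:
        raise ValueError("s_min must be < s_max")
    s = np.asarray(s, dtype=float)
    if np.any(s < s_min - 1e-12) or np.any(s > s_max + 1e-12):
        raise ValueError(f"suitability outside [{s_min}, {s_max}]")
    r = 1.0 + 99.0 * (s_max - s) / (s_max - s_min)
    return float(r) if r.ndim == 0 else r


def resistance_to_suitability(r, s_min: float, s_max: float):
    """Inverse of :func:`suitability_to_resistance` on [1, 100]."""
    r = np.asarray(r, dtype=float)
    s = s_max - (r - 1.0) * (s_max - s_min) / 99.0
    return float(s) if s.ndim == 0 else s


def _bilinear_coarsen(values: np.ndarray, factor: int) -> np.ndarray:
    """Resample by an integer factor: bilinear interpolation of the source
    field at the coarse-cell centres."""
    rows, cols = values.shape
    out_rows, out_cols = rows // factor, cols // factor
    rr = np.arange(out_rows) * factor + (factor - 1) / 2.0
    cc = np.arange(out_cols) * factor + (factor - 1) / 2.0
    coords = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(
        values.astype(float), coords, order=1, mode="nearest"
    )


def build_resistance(
    landcover: LandCoverGrid,
    table: SuitabilityTable,
    target_cell_size: float | None = None,
) -> ResistanceGrid:
    """Per-class resistance lookup followed by bilinear coarsening.

    (s_min, s_max) are the observed min/max class *means* from the panel
    table, so the best observed class maps to resistance exactly 1 and the
    worst to exactly 100.  ``target_cell_size`` must be an integer multiple
    of the source cell size (equal means no resampling).
    """
    src = landcover.raster
    present = np.unique(src.values[src.data_mask()])
    missing = [c for c in present.tolist() if c not in table.table.index]
    if missing:
        raise ValueError(f"classes missing from suitability table: {missing}")
    s_min, s_max = table.s_min, table.s_max
    lookup = {
        int(code): suitability_to_resistance(
            table.mean_suitability(code), s_min, s_max
        )
        for code in table.table.index
    }
    res = np.empty(src.shape, dtype=float)
    for code, r in lookup.items():
        res[src.values == code] = r

    cell = src.cell_size
    if target_cell_size is None or np.isclose(target_cell_size, cell):
        out = RasterGrid(res, cell, src.origin, src.nodata)
    else:
        factor = target_cell_size / cell
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(
                f"target cell size {target_cell_size} is not an integer multiple "
                f"of source cell size {cell}"
            )
        res = np.clip(_bilinear_coarsen(res, int(round(factor))), 1.0, 100.0)
        out = RasterGrid(res, target_cell_size, src.origin, src.nodata)
    return ResistanceGrid(out, landcover.epoch_label)


def project_future_resistance(
    r_now: ResistanceGrid,
    risk: RasterGrid,
    r_transition: float,
    mode: str = "literal",
    epoch_label: str = "",
) -> ResistanceGrid:
    """Project resistance one epoch forward from a deforestation-risk map.

    ``mode="literal"``: ``r_future = min(100, r_now + risk * r_transition)``.
    ``mode="expectation"``: ``r_future = r_now + risk * (r_transition - r_now)``
    (the expected resistance if each cell converts with probability = risk).
    Risk-0 cells are unchanged in both modes.
    """
    check_aligned(r_now.raster, risk)
    p = np.asarray(risk.values, dtype=float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("risk must lie in [0, 1]")
    if not 1.0 <= r_transition <= 100.0:
        raise ValueError("r_transition must lie in [1, 100]")
    r = np.asarray(r_now.raster.values, dtype=float)
    if mode == "literal":
        out = np.minimum(100.0, r + p * r_transition)
    elif mode == "expectation":
        out = r + p * (r_transition - r)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return ResistanceGrid(r_now.raster.copy(out), epoch_label or r_now.epoch_label)


def _weight_grid(r: ResistanceGrid, seed: int) -> np.ndarray:
    """u / r with u ~ Uniform(0,1) i.i.d. per cell, NaN off the data mask."""
    rng = np.random.default_rng(seed)
    u = rng.random(r.raster.shape)
    w = u / np.asarray(r.raster.values, dtype=float)
    w[~r.raster.data_mask()] = np.nan
    return w


def seed_source_points(r: ResistanceGrid, n_target: int, seed: int) -> SourcePointSet:
    """Select the ``n_target`` cells with the largest u/r weight.

    The stored threshold is the n_target-th largest weight; ties are broken
    by row-major cell order, so the selection is exactly reproducible.
    """
    w = _weight_grid(r, seed)
    flat = w.ravel()
    valid = ~np.isnan(flat)
    if n_target > valid.sum():
        raise ValueError(f"n_target {n_target} exceeds {valid.sum()} valid cells")
    order = np.argsort(np.where(valid, -flat, np.inf), kind="stable")
    chosen = order[:n_target]
    threshold = float(flat[chosen[-1]])
    pts = np.column_stack(np.unravel_index(np.sort(chosen), w.shape))
    return SourcePointSet(pts, threshold, seed, r.epoch_label, n_target)


def reapply_threshold(r: ResistanceGrid, threshold: float, seed: int) -> SourcePointSet:
    """Apply a stored threshold (and the same random grid) to another epoch.

    Cells with ``u / r >= threshold`` are selected, so re-applying an
    epoch's own threshold reproduces its point set exactly, and an epoch
    with uniformly higher resistance yields no more points.
    """
    w = _weight_grid(r, seed)
    mask = w >= threshold
    pts = np.column_stack(np.nonzero(mask))
    return SourcePointSet(pts, threshold, seed, r.epoch_label, None)
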