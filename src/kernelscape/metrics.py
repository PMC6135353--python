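"""Binary habitat maps and landscape pattern metrics.

Connectivity surfaces (kernel density, smoothed path density) are cut into
binary connected-habitat maps at a percentile of a *reference* surface —
conventionally the first epoch — so that later epochs are measured against
the same absolute threshold.  The percentile is taken over the reference's
positive values by default (zero cells dominate kernel surfaces and would
collapse low percentiles to 0); the all-cells variant is available.

On the binary maps the four pattern metrics of the analysis are computed:

* PLAND — habitat cells as a percentage of the landscape;
* LPI — largest patch as a percentage of the landscape;
* NP — number of 8-connected patches;
* correlation length — area-weighted mean radius of gyration (metres),
  the average distance an organism can travel within a patch before
  hitting its boundary, from a random start.

Radius of gyration follows the FRAGSTATS GYRATE definition: the mean
Euclidean distance from each patch cell centre to the patch centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterGrid, check_aligned

__all__ = [
    "BinaryHabitatMap",
    "PatchSet",
    "MetricsReport",
    "threshold_to_binary",
    "label_patches",
    "compute_metrics",
    "relative_change",
]

_STRUCTURE_8 = np.ones((3, 3), dtype=int)


@dataclass
class BinaryHabitatMap:
    raster: RasterGrid  # values in {0, 1} on valid cells
    threshold_value: float
    percentile: float
    reference_epoch: str = ""


@dataclass
class PatchSet:
    """Labelled patches with per-patch geometry.

    ``patches`` has one row per patch: label, area_cells, area_m2,
    centroid_x, centroid_y (metres from the grid origin), gyrate_m.
    """

    labels: RasterGrid  # patch ids, 0 = background
    patches: pd.DataFrame
    cell_size: float

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def habitat_cells(self) -> int:
        return int(self.patches["area_cells"].sum()) if len(self.patches) else 0


@dataclass
class MetricsReport:
    pland: float  # % of landscape
    lpi: float  # % of landscape
    n_patches: int
    correlation_length: float  # metres

    def as_dict(self) -> dict:
        return {
            "pland": self.pland,
            "lpi": self.lpi,
            "n_patches": self.n_patches,
            "correlation_length": self.correlation_length,
        }


def threshold_to_binary(
    surface: RasterGrid,
    reference: RasterGrid,
    percentile: float,
    positive_only: bool = True,
    reference_epoch: str = "",
) -> BinaryHabitatMap:
    """Binary habitat: 1 where surface exceeds the reference percentile.

    The threshold is the linear-interpolation quantile of the reference's
    positive values (or of all valid cells with ``positive_only=False``);
    cells strictly greater than the threshold become 1.
    """
    check_aligned(surface, reference)
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    ref = np.asarray(reference.values, dtype=float)[reference.data_mask()]
    if positive_only:
        ref = ref[ref > 0]
    if ref.size == 0:
        raise ValueError("reference surface has no positive values")
    thr = float(np.percentile(ref, percentile))
    binary = (np.asarray(surface.values, dtype=float) > thr).astype(np.int8)
    binary[~surface.data_mask()] = 0
    return BinaryHabitatMap(surface.copy(binary), thr, percentile, reference_epoch)


def label_patches(binary: BinaryHabitatMap, connectivity: int = 8) -> PatchSet:
    """Connected components and per-patch geometry.

    8-adjacency by default (cells touching at a corner join);
    ``connectivity=4`` restricts to edge-sharing.
    """
    structure = _STRUCTURE_8 if connectivity == 8 else None
    labels, n = ndimage.label(binary.raster.values == 1, structure=structure)
    cell = binary.raster.cell_size
    rows_list = []
    if n:
        rr, cc = np.nonzero(labels)
        lab = labels[rr, cc]
        # cell-centre coordinates in metres relative to the grid origin
        x = (cc + 0.5) * cell
        y = (rr + 0.5) * cell
        area = np.bincount(lab, minlength=n + 1)[1:]
        cx = np.bincount(lab, weights=x, minlength=n + 1)[1:] / area
        cy = np.bincount(lab, weights=y, minlength=n + 1)[1:] / area
        d = np.hypot(x - cx[lab - 1], y - cy[lab - 1])
        gyrate = np.bincount(lab, weights=d, minlength=n + 1)[1:] / area
        for i in range(n):
            rows_list.append(
                {
                    "label": i + 1,
                    "area_cells": int(area[i]),
                    "area_m2": float(area[i]) * cell * cell,
                    "centroid_x": float(cx[i]),
                    "centroid_y": float(cy[i]),
                    "gyrate_m": float(gyrate[i]),
                }
            )
    patches = pd.DataFrame(
        rows_list,
        columns=["label", "area_cells", "area_m2", "centroid_x", "centroid_y", "gyrate_m"],
    )
    return PatchSet(binary.raster.copy(labels), patches, cell)


def compute_metrics(patches: PatchSet, landscape_cells: int) -> MetricsReport:
    """PLAND, LPI, patch count and correlation length for one binary map."""
    if landscape_cells <= 0:
        raise ValueError("landscape_cells must be > 0")
    if patches.n_patches == 0:
        return MetricsReport(0.0, 0.0, 0, 0.0)
    areas = patches.patches["area_cells"].to_numpy(dtype=float)
    gyr = patches.patches["gyrate_m"].to_numpy(dtype=float)
    pland = 100.0 * areas.sum() / landscape_cells
    lpi = 100.0 * areas.max() / landscape_cells
    corr_len = float((areas / areas.sum()) @ gyr)
    return MetricsReport(float(pland), float(lpi), int(patches.n_patches), corr_len)


def relative_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``."""
    if before == 0:
        raise ValueError("relative change undefined for before = 0")
    return 100.0 * (after - before) / before
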