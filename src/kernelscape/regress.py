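"""Predicting local genetic diversity from connectivity surfaces.

The full chain (all-pairs least-cost paths, individual-based simulation)
is computationally heavy; a practical question is whether cheap landscape
surfaces predict the simulated local diversity directly.  This module
assembles a per-point predictor table — focal-mean resistance in a 10 km
window, smoothed least-cost-path density, cumulative resistant kernel
density — and fits ordinary least squares models of local allelic
richness or observed heterozygosity on each single predictor and on all
three together ("global" model).  For Gaussian least squares the deviance
explained equals R^2 = 1 - RSS/TSS, which makes the single-variable vs
global comparison well defined.

The kernel predictor enters as a reciprocal, ``1 / (kernel + eps)`` with
eps the smallest positive kernel value, to linearize its curvilinear
relationship with diversity.  LOWESS curves (span 2/3) are emitted as
(x, fitted) pairs for scatterplot overlays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .connectivity import KernelSurface, PathDensitySurface, focal_mean
from .localdiv import LocalDiversitySurface
from .raster import RasterGrid, check_aligned
from .resistance import ResistanceGrid, SourcePointSet

__all__ = [
    "ModelComparison",
    "assemble_predictor_table",
    "fit_diversity_models",
]

PREDICTORS = ["focal_mean_resistance", "lcp_density", "kernel_density"]


@dataclass
class ModelComparison:
    """Per-model coefficients and deviance explained.

    ``models``: rows = resistance-only, lcp-only, kernel-only, global;
    columns model, predictors, deviance_explained, plus one column per
    coefficient (NaN where absent).  ``lowess_curves`` maps predictor name
    to an (x, fitted) DataFrame.
    """

    models: pd.DataFrame
    response: str
    kernel_epsilon: float
    lowess_curves: dict = field(default_factory=dict)

    def deviance_explained(self, model: str) -> float:
        return float(
            self.models.set_index("model").loc[model, "deviance_explained"]
        )


def assemble_predictor_table(
    points: SourcePointSet,
    resistance: ResistanceGrid,
    kernel: KernelSurface,
    lcp_smoothed: PathDensitySurface,
    diversity: LocalDiversitySurface,
    focal_radius: float = 10_000.0,
) -> pd.DataFrame:
    """One row per point with non-missing local diversity.

    Focal-mean resistance comes from a circular window of ``focal_radius``
    metres; kernel and path density are sampled at the point cell
    (nearest-cell, no interpolation — all surfaces share the grid).
    """
    check_aligned(resistance.raster, kernel.raster, lcp_smoothed.raster)
    div = diversity.table.dropna(subset=["alleles_per_locus", "ho"])
    if div.empty:
        raise ValueError("no points with non-missing local diversity")
    fm = focal_mean(resistance.raster, focal_radius)
    rows = []
    for _, rec in div.iterrows():
        p = int(rec["point"])
        r, c = points.points[p]
        rows.append(
            {
                "point": p,
                "focal_mean_resistance": float(fm.values[r, c]),
                "lcp_density": float(lcp_smoothed.raster.values[r, c]),
                "kernel_density": float(kernel.raster.values[r, c]),
                "local_alleles": float(rec["alleles_per_locus"]),
                "local_ho": float(rec["ho"]),
            }
        )
    return pd.DataFrame(rows)


def _transform_kernel(k: np.ndarray, eps: float) -> np.ndarray:
    return 1.0 / (k + eps)


def fit_diversity_models(
    table: pd.DataFrame,
    response: str = "alleles",
    kernel_transform: str = "reciprocal",
    lowess_frac: float = 2.0 / 3.0,
) -> ModelComparison:
    """OLS single-predictor and global models with deviance explained.

    ``response`` is ``"alleles"`` (local mean alleles per locus) or
    ``"ho"`` (local observed heterozygosity).
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows")
    ycol = {"alleles": "local_alleles", "ho": "local_ho"}.get(response)
    if ycol is None:
        raise ValueError(f"unknown response {response!r}")
    y = table[ycol].to_numpy(dtype=float)

    kern = table["kernel_density"].to_numpy(dtype=float)
    pos = kern[kern > 0]
    eps = float(pos.min()) if pos.size else 1.0
    x_all = {
        "focal_mean_resistance": table["focal_mean_resistance"].to_numpy(dtype=float),
        "lcp_density": table["lcp_density"].to_numpy(dtype=float),
        "kernel_density": (
            _transform_kernel(kern, eps) if kernel_transform == "reciprocal" else kern
        ),
    }
    for name, x in x_all.items():
        if np.isclose(np.var(x), 0.0):
            raise ValueError(f"predictor {name} is constant")

    def fit(names: list[str]) -> tuple[dict, float]:
        X = sm.add_constant(np.column_stack([x_all[nm] for nm in names]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"singular design for predictors {names}")
        res = sm.OLS(y, X).fit()
        coefs = {"const": float(res.params[0])}
        coefs.update({nm: float(b) for nm, b in zip(names, res.params[1:])})
        return coefs, float(res.rsquared)

    rows = []
    for name in PREDICTORS:
        coefs, r2 = fit([name])
        rows.append(
            {"model": name, "predictors": name, "deviance_explained": r2, **coefs}
        )
    coefs, r2 = fit(PREDICTORS)
    rows.append(
        {
            "model": "global",
            "predictors": "+".join(PREDICTORS),
            "deviance_explained": r2,
            **coefs,
        }
    )
    models = pd.DataFrame(rows)

    curves = {}
    for name in PREDICTORS:
        fitted = lowess(y, x_all[name], frac=lowess_frac, return_sorted=True)
        curves[name] = pd.DataFrame(fitted, columns=["x", "fitted"])
    return ModelComparison(models, response, eps, curves)
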