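"""Synthetic land cover, deforestation risk and expert panels.

The downstream analysis (resistance mapping, connectivity, landscape
genetics) needs categorical land-cover mosaics over three dates with
contiguous forest blocks, progressive forest loss concentrated at patch
edges, an edge-weighted deforestation-risk surface, and an expert panel
with high inter-rater agreement and per-class missingness.  The
generators here produce exactly those statistical structures so the whole
chain is testable on self-contained fixtures.

Patch structure is made by thresholding Gaussian-smoothed white noise at
the class-fraction quantiles: the smoothed field is continuous, so the
realized class fractions track the requested ones closely, and the
smoothing length (``patchiness``, in cells) controls patch size.  All
generators are bit-reproducible from their integer seed.

The deforestation-risk generator is a simple edge-distance decay blend; it
emulates the qualitative pattern of loss concentrating along forest-patch
edges and is *not* a fitted deforestation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .experts import ExpertRatingSet
from .raster import RasterGrid, check_aligned

__all__ = [
    "ClassEntry",
    "ClassTable",
    "LandCoverGrid",
    "SyntheticScenario",
    "default_class_table",
    "generate_landcover",
    "degrade_landcover",
    "generate_deforestation_risk",
    "generate_expert_ratings",
    "make_demo_scenario",
    "DEMO_TRUE_SUITABILITY",
]


@dataclass(frozen=True)
class ClassEntry:
    code: int
    name: str
    is_forest: bool
    transition_target: int | None = None


@dataclass
class ClassTable:
    """Land-cover class legend.

    Forest classes carry a ``transition_target``: the class a deforested
    cell becomes.  Exactly one distinct target class (the
    plantations/regrowth analogue) must be named, and it must be
    non-forest.
    """

    entries: list[ClassEntry]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be unique")
        targets = {e.transition_target for e in self.entries if e.transition_target is not None}
        if len(targets) != 1:
            raise ValueError(
                "exactly one deforestation transition target class must be named"
            )
        (target,) = targets
        if target not in codes:
            raise ValueError(f"transition target {target} is not a class code")
        by_code = {e.code: e for e in self.entries}
        if by_code[target].is_forest:
            raise ValueError("transition target must be a non-forest class")
        if not any(e.is_forest for e in self.entries):
            raise ValueError("need at least one forest class")
        if not any(not e.is_forest for e in self.entries):
            raise ValueError("need at least one non-forest class")

    @property
    def codes(self) -> list[int]:
        return [e.code for e in self.entries]

    @property
    def forest_codes(self) -> list[int]:
        return [e.code for e in self.entries if e.is_forest]

    @property
    def transition_target(self) -> int:
        return next(
            e.transition_target for e in self.entries if e.transition_target is not None
        )

    def forest_mask(self, values: np.ndarray) -> np.ndarray:
        return np.isin(values, self.forest_codes)


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster plus its legend and an epoch label."""

    raster: RasterGrid
    classes: ClassTable
    epoch_label: str = ""

    def __post_init__(self) -> None:
        valid = self.raster.data_mask()
        present = np.unique(self.raster.values[valid])
        unknown = set(present.tolist()) - set(self.classes.codes)
        if unknown:
            raise ValueError(f"raster contains unknown class codes {sorted(unknown)}")

    def forest_mask(self) -> np.ndarray:
        return self.classes.forest_mask(self.raster.values) & self.raster.data_mask()

    def forest_fraction(self) -> float:
        valid = self.raster.data_mask()
        return float(self.forest_mask().sum() / valid.sum())


@dataclass
class SyntheticScenario:
    """Three-date synthetic study system.

    ``grids`` are the land-cover maps at t0 < t1 < t2; ``risk`` is the
    t1 -> t2 deforestation-probability surface (zero off forest); ``panel``
    the synthetic expert rating set; ``seed`` the master seed that produced
    everything.
    """

    grids: tuple[LandCoverGrid, LandCoverGrid, LandCoverGrid]
    risk: RasterGrid
    panel: ExpertRatingSet
    seed: int

    def __post_init__(self) -> None:
        check_aligned(*(g.raster for g in self.grids), self.risk)
        fr = [g.forest_fraction() for g in self.grids]
        if not (fr[0] >= fr[1] >= fr[2]):
            raise ValueError(f"forest fraction must be non-increasing, got {fr}")


def default_class_table() -> ClassTable:
    """A compact Borneo-like legend: three forest classes, one transition
    target (plantations/regrowth) and three other non-forest classes."""
    return ClassTable(
        [
            ClassEntry(1, "water", False),
            ClassEntry(2, "lowland_forest", True, transition_target=5),
            ClassEntry(3, "peat_swamp_forest", True, transition_target=5),
            ClassEntry(4, "lower_montane_forest", True, transition_target=5),
            ClassEntry(5, "plantations_regrowth", False),
            ClassEntry(6, "lowland_mosaic", False),
            ClassEntry(7, "urban", False),
        ]
    )


def generate_landcover(
    shape: tuple[int, int],
    cell_size: float,
    class_fractions: dict[int, float],
    patchiness: float,
    seed: int,
    classes: ClassTable | None = None,
    epoch_label: str = "t0",
) -> LandCoverGrid:
    """Generate a categorical mosaic with contiguous patches.

    White noise is smoothed with a Gaussian filter of sigma ``patchiness``
    (cells) and cut at the class-fraction quantiles; classes are assigned
    in the dict's insertion order along the smoothed-field axis, so classes
    listed adjacently tend to adjoin spatially.
    """
    classes = classes or default_class_table()
    fracs = np.array(list(class_fractions.values()), dtype=float)
    codes = list(class_fractions.keys())
    unknown = set(codes) - set(classes.codes)
    if unknown:
        raise ValueError(f"unknown class codes {sorted(unknown)}")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {fracs.sum()!r}")
    if not patchiness > 0:
        raise ValueError("patchiness must be > 0")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=patchiness)
    cum = np.cumsum(fracs)[:-1]
    thresholds = np.quantile(smooth, cum) if len(cum) else np.array([])
    idx = np.searchsorted(thresholds, smooth, side="right")
    values = np.asarray(codes, dtype=np.int64)[idx]
    return LandCoverGrid(RasterGrid(values, cell_size), classes, epoch_label)


def degrade_landcover(
    grid: LandCoverGrid, risk: RasterGrid, seed: int, epoch_label: str | None = None
) -> LandCoverGrid:
    """Realize one epoch of forest loss.

    Each forest cell independently converts to the legend's transition
    target with probability equal to the risk surface at that cell;
    non-forest cells never change.
    """
    check_aligned(grid.raster, risk)
    r = np.asarray(risk.values, dtype=float)
    if np.nanmin(r) < 0 or np.nanmax(r) > 1:
        raise ValueError("risk must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(grid.raster.shape)
    flip = grid.forest_mask() & (u < r)
    values = grid.raster.values.copy()
    values[flip] = grid.classes.transition_target
    return LandCoverGrid(
        grid.raster.copy(values),
        grid.classes,
        epoch_label if epoch_label is not None else grid.epoch_label,
    )


def generate_deforestation_risk(
    grid: LandCoverGrid,
    edge_weight: float,
    base_rate: float,
    seed: int,
    decay_cells: float = 2.0,
    noise_amp: float = 0.2,
    floor: float = 0.0,
) -> RasterGrid:
    """Edge-concentrated deforestation probability for forest cells.

    Risk is ``base_rate`` plus an edge component that decays exponentially
    with distance (in cells) from the nearest non-forest cell, scaled by
    ``edge_weight`` and jittered by a seeded multiplicative noise; clipped
    to [0, 1] and exactly zero off forest.  With ``edge_weight = 0``, or on
    a landscape with no forest edge at all, every forest cell gets exactly
    ``base_rate``.

    ``floor`` truncates probabilities below the cutoff to exactly zero,
    emulating the sparse-risk structure of fitted deforestation models
    (remote interior forest gets predicted risk 0, not a small positive
    number).  Truncation applies only when an edge component is present,
    so the uniform ``edge_weight = 0`` limit is unaffected.

    The edge distance is measured to the cleared *frontier*: non-forest
    specks smaller than a 2x2 block (single-cell canopy gaps) are removed
    by binary opening before the distance transform, since deforestation
    pressure tracks the advancing clearing front, not isolated gaps.
    """
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError("base_rate must lie in [0, 1]")
    forest = grid.forest_mask()
    risk = np.zeros(grid.raster.shape, dtype=float)
    risk[forest] = base_rate
    frontier = ndimage.binary_opening(~forest, structure=np.ones((2, 2), dtype=bool))
    if edge_weight != 0.0 and forest.any() and frontier.any():
        # distance (cells) to the frontier; forest cells adjacent to it have d = 1
        d = ndimage.distance_transform_edt(~frontier)
        decay = np.exp(-(d - 1.0) / decay_cells)
        rng = np.random.default_rng(seed)
        jitter = 1.0 + noise_amp * (2.0 * rng.random(grid.raster.shape) - 1.0)
        extra = edge_weight * (1.0 - base_rate) * decay * jitter
        total = np.clip(base_rate + extra, 0.0, 1.0)
        total[total < floor] = 0.0
        risk[forest] = total[forest]
    return grid.raster.copy(risk)


def generate_expert_ratings(
    true_suitability: dict[int, float],
    n_experts: int,
    rating_sd: float,
    missing_prob: float,
    density_slope: float,
    density_sd: float,
    seed: int,
) -> ExpertRatingSet:
    """Simulate a rating panel around known class suitabilities.

    Each expert carries a Gaussian bias (sd ``rating_sd``) and each
    (expert, class) rating adds independent Gaussian noise (same sd); the
    sum is rounded to the integer 1-5 scale and clipped.  Each
    (expert, class) response is missing independently with probability
    ``missing_prob``.  Density estimates are ``density_slope x truth``
    plus Gaussian noise (sd ``density_sd``), floored at zero.
    """
    if n_experts < 2:
        raise ValueError("need at least 2 experts")
    if not 0.0 <= missing_prob < 1.0:
        raise ValueError("missing_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    codes = list(true_suitability.keys())
    truths = np.array([true_suitability[c] for c in codes], dtype=float)
    bias = rng.normal(0.0, rating_sd, size=n_experts)
    noise = rng.normal(0.0, rating_sd, size=(n_experts, len(codes)))
    raw = truths[None, :] + bias[:, None] + noise
    ratings = np.clip(np.round(raw), 1, 5)
    densities = np.maximum(
        density_slope * truths[None, :]
        + rng.normal(0.0, density_sd, size=(n_experts, len(codes))),
        0.0,
    )
    missing = rng.random((n_experts, len(codes))) < missing_prob
    records = []
    for i in range(n_experts):
        for j, code in enumerate(codes):
            if missing[i, j]:
                records.append((f"E{i + 1:02d}", code, np.nan, np.nan))
            else:
                records.append(
                    (f"E{i + 1:02d}", code, float(ratings[i, j]), float(densities[i, j]))
                )
    df = pd.DataFrame(
        records, columns=["expert_id", "class_code", "suitability", "density_per_100km2"]
    )
    return ExpertRatingSet(df)


# True class suitabilities for the packaged demo scenario; chosen to mirror
# the characteristic ordering of a Bornean legend (lowland forest best,
# urban worst, plantations intermediate).
DEMO_TRUE_SUITABILITY: dict[int, float] = {
    1: 1.1,  # water
    2: 4.5,  # lowland forest
    3: 3.3,  # peat swamp forest
    4: 4.2,  # lower montane forest
    5: 2.0,  # plantations / regrowth
    6: 2.1,  # lowland mosaic
    7: 1.0,  # urban
}

# Insertion order controls spatial adjacency along the smoothed field:
# the forest classes occupy the upper-middle quantiles and so form a few
# large massifs fringed by mosaic and plantation classes.
DEMO_CLASS_FRACTIONS: dict[int, float] = {
    1: 0.05,  # water
    6: 0.10,  # lowland mosaic
    5: 0.10,  # plantations
    2: 0.40,  # lowland forest
    3: 0.15,  # peat swamp forest
    4: 0.10,  # montane forest
    7: 0.10,  # urban + open analogue
}


def make_demo_scenario(
    seed: int,
    shape: tuple[int, int] = (120, 120),
    cell_size: float = 1000.0,
    patchiness: float = 12.0,
    n_experts: int = 13,
    rating_sd: float = 0.35,
    missing_prob: float = 0.22,
) -> SyntheticScenario:
    """The packaged three-epoch study system.

    Epoch 1 loss is modest and mildly edge-weighted; epoch 2 loss is much
    heavier and strongly edge-concentrated, so forest loss accelerates
    between the intervals (the regime the full analysis is designed to
    detect).  The expert panel is a low-noise 13-member panel with
    per-class missingness, i.e. the high-agreement regime.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    t0 = generate_landcover(
        shape, cell_size, DEMO_CLASS_FRACTIONS, patchiness, seeds[0], epoch_label="t0"
    )
    risk1 = generate_deforestation_risk(t0, edge_weight=0.5, base_rate=0.02, seed=seeds[1])
    t1 = degrade_landcover(t0, risk1, seeds[2], epoch_label="t1")
    risk2 = generate_deforestation_risk(
        t1, edge_weight=1.0, base_rate=0.0, seed=seeds[3], decay_cells=2.0, floor=0.05
    )
    t2 = degrade_landcover(t1, risk2, seeds[4], epoch_label="t2")
    panel = generate_expert_ratings(
        DEMO_TRUE_SUITABILITY,
        n_experts=n_experts,
        rating_sd=rating_sd,
        missing_prob=missing_prob,
        density_slope=0.6,
        density_sd=0.25,
        seed=seeds[0] ^ 0x5EED,
    )
    return SyntheticScenario((t0, t1, t2), risk2, panel, seed)
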