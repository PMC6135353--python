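"""Expert-panel aggregation and agreement statistics.

Landscape resistance for an elusive carnivore is rarely measurable
directly; a standard substitute is a panel of field experts rating the
habitat suitability of each land-cover class on an interval 1-5 scale
(5 = best habitat).  This module aggregates such a panel into per-class
summary scores, quantifies inter-rater agreement with the two-way mixed,
consistency-form intraclass correlation (Shrout-Fleiss ICC(3,1) for a
single rater and ICC(3,k) for the k-rater average), and checks internal
coherence of the panel by regressing the experts' per-class density
estimates (individuals per 100 km^2) on the mean suitability scores.

Experts may decline to rate classes they have no experience with, so the
rating matrix is generally incomplete.  ICC is computed either on the
complete-case submatrix (default: drop experts with any missing class) or
from an unbalanced additive two-way fit over all available ratings
(``handling="pairwise"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpertRatingSet",
    "SuitabilityTable",
    "AgreementReport",
    "ICCUndefinedError",
    "aggregate_ratings",
    "icc_two_way_mixed",
    "suitability_density_fit",
    "agreement_report",
]


class ICCUndefinedError(ValueError):
    """ICC cannot be formed (no between-class variance or too few raters)."""


RATING_COLUMNS = ["expert_id", "class_code", "suitability", "density_per_100km2"]


@dataclass
class ExpertRatingSet:
    """Long-format expert x land-cover-class ratings.

    ``records`` has columns ``expert_id``, ``class_code``, ``suitability``
    (integer 1-5 or NaN = missing) and ``density_per_100km2`` (>= 0 or NaN).
    (expert, class) pairs are unique.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in RATING_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"rating table missing columns {missing}")
        if df.duplicated(["expert_id", "class_code"]).any():
            raise ValueError("duplicate (expert_id, class_code) pairs")
        s = df["suitability"].dropna()
        if len(s) and ((s < 1) | (s > 5)).any():
            raise ValueError("suitability ratings must lie in [1, 5]")

    def to_matrix(self) -> pd.DataFrame:
        """Experts (rows) x classes (columns) suitability matrix, NaN = missing."""
        return self.records.pivot(
            index="expert_id", columns="class_code", values="suitability"
        )

    def to_csv(self, path: str) -> None:
        self.records[RATING_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "ExpertRatingSet":
        return cls(pd.read_csv(path))


@dataclass
class SuitabilityTable:
    """Per-class panel summary: n, min, max, population sd, means.

    ``table`` is indexed by class_code with columns ``n_responses``,
    ``min_score``, ``max_score``, ``sd``, ``mean_suitability``,
    ``mean_density``.  ``excluded`` lists classes that received zero
    responses and were dropped.
    """

    table: pd.DataFrame
    excluded: list = field(default_factory=list)

    def mean_suitability(self, class_code) -> float:
        return float(self.table.loc[class_code, "mean_suitability"])

    @property
    def s_min(self) -> float:
        """Lowest observed class mean (worst habitat actually rated)."""
        return float(self.table["mean_suitability"].min())

    @property
    def s_max(self) -> float:
        """Highest observed class mean (best habitat actually rated)."""
        return float(self.table["mean_suitability"].max())

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path: str) -> "SuitabilityTable":
        return cls(pd.read_csv(path, index_col=0))


@dataclass
class AgreementReport:
    icc_single: float
    icc_average: float
    r2_density: float
    n_complete: int

    def to_csv(self, path: str) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, index=False)


def aggregate_ratings(ratings: ExpertRatingSet) -> SuitabilityTable:
    """Per-class mean/min/max/sd over non-missing ratings.

    The standard deviation uses the population (divide-by-n) form.  Classes
    with zero responses are excluded and listed in ``excluded``.
    """
    df = ratings.records
    if df["suitability"].dropna().empty:
        raise ValueError("empty rating set: no non-missing suitability ratings")
    rows = {}
    excluded = []
    for code, grp in df.groupby("class_code", sort=True):
        s = grp["suitability"].dropna().to_numpy(dtype=float)
        if s.size == 0:
            excluded.append(code)
            continue
        d = grp["density_per_100km2"].dropna().to_numpy(dtype=float)
        rows[code] = {
            "n_responses": int(s.size),
            "min_score": float(s.min()),
            "max_score": float(s.max()),
            "sd": float(np.std(s)),  # population form (ddof=0)
            "mean_suitability": float(s.mean()),
            "mean_density": float(d.mean()) if d.size else np.nan,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "class_code"
    return SuitabilityTable(table, excluded)


def _icc_from_mean_squares(ms_rows: float, ms_err: float, k: float) -> tuple[float, float]:
    if ms_rows <= 0 or np.isclose(ms_rows, 0.0):
        raise ICCUndefinedError("zero between-class variance: ICC undefined")
    icc_single = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    icc_average = (ms_rows - ms_err) / ms_rows
    return float(icc_single), float(icc_average)


def icc_two_way_mixed(
    matrix, handling: str = "complete_case"
) -> tuple[float, float]:
    """Two-way mixed, consistency-form ICC for raters-by-targets data.

    Parameters
    ----------
    matrix
        Experts (rows) x classes (columns) array or DataFrame; NaN = missing.
        Classes are the rated targets ("rows" of the ANOVA decomposition),
        experts the fixed raters.
    handling
        ``"complete_case"`` drops experts with any missing class before the
        balanced two-way ANOVA.  ``"pairwise"`` keeps all available ratings
        and uses an unbalanced additive (class + expert) least-squares fit,
        with the rater count k replaced by the mean raters per class.

    Returns
    -------
    (icc_single, icc_average)
        ICC(3,1) = (MS_C - MS_E) / (MS_C + (k-1) MS_E) and
        ICC(3,k) = (MS_C - MS_E) / MS_C, where MS_C is the between-class
        mean square and MS_E the residual mean square.
    """
    x = np.asarray(
        matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix, dtype=float
    )
    if x.ndim != 2:
        raise ValueError("rating matrix must be 2-D (experts x classes)")

    if handling == "complete_case":
        x = x[~np.isnan(x).any(axis=1)]
        k, n = x.shape  # k experts, n classes
        if k < 2:
            raise ICCUndefinedError("fewer than 2 complete experts")
        if n < 2:
            raise ICCUndefinedError("fewer than 2 classes")
        grand = x.mean()
        class_means = x.mean(axis=0)
        expert_means = x.mean(axis=1)
        ss_total = ((x - grand) ** 2).sum()
        ss_class = k * ((class_means - grand) ** 2).sum()
        ss_expert = n * ((expert_means - grand) ** 2).sum()
        ss_err = ss_total - ss_class - ss_expert
        ms_class = ss_class / (n - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        return _icc_from_mean_squares(ms_class, max(ms_err, 0.0), k)

    if handling == "pairwise":
        rows, cols = np.nonzero(~np.isnan(x))
        y = x[rows, cols]
        n_exp = len(np.unique(rows))
        n_cls = len(np.unique(cols))
        if n_exp < 2 or n_cls < 2:
            raise ICCUndefinedError("fewer than 2 experts or classes after missingness")
        # additive two-way fit by least squares on indicator design
        import numpy.linalg as la

        def design(with_class: bool) -> np.ndarray:
            blocks = [np.ones((len(y), 1))]
            for i in np.unique(rows)[1:]:
                blocks.append((rows == i).astype(float)[:, None])
            if with_class:
                for j in np.unique(cols)[1:]:
                    blocks.append((cols == j).astype(float)[:, None])
            return np.hstack(blocks)

        def rss(X: np.ndarray) -> tuple[float, int]:
            beta, *_ = la.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return float(resid @ resid), X.shape[1]

        rss_full, p_full = rss(design(True))
        rss_red, _ = rss(design(False))
        df_err = len(y) - p_full
        if df_err <= 0:
            raise ICCUndefinedError("no residual degrees of freedom")
        ms_err = rss_full / df_err
        ms_class = (rss_red - rss_full) / (n_cls - 1)
        k_eff = len(y) / n_cls
        return _icc_from_mean_squares(ms_class, max(ms_err, 0.0), k_eff)

    raise ValueError(f"unknown missingness handling {handling!r}")


def suitability_density_fit(table: SuitabilityTable) -> float:
    """R^2 of OLS of per-class mean density on mean suitability."""
    t = table.table.dropna(subset=["mean_suitability", "mean_density"])
    if len(t) < 3:
        raise ValueError("need at least 3 classes with both means present")
    x = t["mean_suitability"].to_numpy(dtype=float)
    y = t["mean_density"].to_numpy(dtype=float)
    sxx = float(((x - x.mean()) ** 2).sum())
    if np.isclose(sxx, 0.0):
        raise ValueError("zero variance in mean suitability")
    syy = float(((y - y.mean()) ** 2).sum())
    if np.isclose(syy, 0.0):
        return 0.0  # constant response: nothing explainable
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    return sxy**2 / (sxx * syy)


def agreement_report(
    ratings: ExpertRatingSet, handling: str = "auto"
) -> AgreementReport:
    """Convenience: ICC + density R^2 for one panel.

    ``handling="auto"`` uses the complete-case ANOVA when at least two
    experts rated every class, and falls back to the unbalanced
    (``pairwise``) fit otherwise — real panels with per-class missingness
    routinely have no fully complete raters.
    """
    matrix = ratings.to_matrix()
    if handling == "auto":
        n_complete_experts = int((~matrix.isna().any(axis=1)).sum())
        handling = "complete_case" if n_complete_experts >= 2 else "pairwise"
    icc_single, icc_average = icc_two_way_mixed(matrix, handling=handling)
    table = aggregate_ratings(ratings)
    try:
        r2 = suitability_density_fit(table)
    except ValueError:
        r2 = np.nan
    n_complete = int((~matrix.isna().any(axis=1)).sum())
    return AgreementReport(icc_single, icc_average, r2, n_complete)
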