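"""Assembly of the cells x features analysis matrix.

Scalar features enter the matrix as-is.  Each distributed (per-process)
feature is expanded into eight distribution statistics describing its center
(mean, median, mode), spread (standard deviation, coefficient of variation,
and the half-width of the t-based 95% confidence interval of the mean) and
shape (skewness, excess kurtosis).  Under the default catalog of 14 scalar
and 12 distributed features this yields 14 + 12*8 = 110 columns.

Downstream steps work on the pooled Z-scored matrix: every column is
standardized to mean 0 and unit sample standard deviation across all cells of
both genotypes and all time points.  For non-negative matrix factorization the
Z-score matrix is shifted per feature so its minimum is exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import COUNT, FeatureDef, default_catalog
from .synthetic import CellRecord

__all__ = [
    "STATISTICS",
    "FeatureDescriptor",
    "FeatureMatrix",
    "summarize_distributed",
    "build_feature_matrix",
    "zscore",
    "select_features",
    "shift_nonnegative",
]

# Expansion statistics, in column order; suffixes follow the reporting
# convention (the confidence-interval half-width is suffixed "_95ci").
STATISTICS = ("mean", "median", "mode", "sdev", "cv", "95ci", "skew", "kurt")

_STAT_KIND = {
    "mean": "Center", "median": "Center", "mode": "Center",
    "sdev": "Spread", "cv": "Spread", "95ci": "Spread",
    "skew": "Shape", "kurt": "Shape",
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Metadata of one column of the analysis matrix."""

    name: str              # column name, e.g. "Branch angle_95ci"
    base_feature: str      # catalog feature it derives from
    compartment: str       # soma | process
    distributed: bool
    statistic: str         # "none" for scalar columns, else one of STATISTICS
    feature_set: str       # annotated label or "unassigned"


def _kde_mode(values: np.ndarray) -> float:
    """Peak of a Gaussian KDE with Silverman bandwidth over a dense grid."""
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    h = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 512)
    return float(grid[np.argmax(kde(grid))])


def _count_mode(values: np.ndarray) -> float:
    """Most frequent value; ties broken toward the lowest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])


def summarize_distributed(values: Sequence[float], count: bool = False) -> dict[str, float]:
    """Distribution statistics of one cell's per-process measurement vector.

    Length-1 vectors get 0 for every spread and shape statistic by convention
    (the caller flags such degenerate cells).  ``count=True`` switches the
    mode estimator from the KDE peak to the most-frequent-value rule.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("summarize_distributed needs a non-empty 1-D vector")
    n = v.size
    mean = float(v.mean())
    median = float(np.median(v))
    if n == 1:
        return {
            "mean": mean, "median": median, "mode": mean,
            "sdev": 0.0, "cv": 0.0, "95ci": 0.0, "skew": 0.0, "kurt": 0.0,
        }
    sd = float(v.std(ddof=1))
    mode = _count_mode(v) if count else _kde_mode(v)
    cv = sd / mean if mean != 0 else 0.0
    ci95 = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    m2 = float(((v - mean) ** 2).mean())
    if m2 == 0:
        skew = kurt = 0.0
    else:
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2 - 3.0
    return {
        "mean": mean, "median": median, "mode": mode,
        "sdev": sd, "cv": cv, "95ci": ci95, "skew": skew, "kurt": kurt,
    }


@dataclass
class FeatureMatrix:
    """Cells x features numeric grid with row and column annotations."""

    values: pd.DataFrame            # index: cell_id; columns: feature columns
    row_meta: pd.DataFrame          # cell_id, mouse_id, genotype, time_days, ...
    col_meta: pd.DataFrame          # one row per column, FeatureDescriptor fields

    def __post_init__(self):
        if list(self.col_meta["name"]) != list(self.values.columns):
            raise ValueError("column metadata out of sync with value columns")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, columns: Sequence[str]) -> "FeatureMatrix":
        cols = list(columns)
        cm = self.col_meta.set_index("name").loc[cols].reset_index()
        return FeatureMatrix(self.values[cols].copy(), self.row_meta.copy(), cm)


def build_feature_matrix(
    cells: Sequence[CellRecord],
    catalog: Optional[Sequence[FeatureDef]] = None,
) -> FeatureMatrix:
    """Expand raw cell records into the analysis matrix.

    The default catalog holds every annotated feature; with 14 scalar and 12
    distributed features the expansion yields 110 columns.
    """
    cat = list(catalog) if catalog is not None else default_catalog()
    if not cells:
        raise ValueError("no cells supplied")
    scalars = [f for f in cat if not f.distributed]
    dists = [f for f in cat if f.distributed]

    missing: set[str] = set()
    for c in cells:
        missing.update(f.name for f in scalars if f.name not in c.scalar_features)
        missing.update(f.name for f in dists if f.name not in c.distributed_features)
    if missing:
        raise KeyError(f"features absent from cell records: {sorted(missing)}")

    col_meta_rows: list[FeatureDescriptor] = []
    for f in scalars:
        col_meta_rows.append(
            FeatureDescriptor(f.name, f.name, f.compartment, False, "none",
                              f.feature_set or "unassigned")
        )
    for f in dists:
        for s in STATISTICS:
            col_meta_rows.append(
                FeatureDescriptor(f"{f.name}_{s}", f.name, f.compartment, True, s,
                                  f.feature_set or "unassigned")
            )

    columns = [d.name for d in col_meta_rows]
    data = np.empty((len(cells), len(columns)))
    for i, c in enumerate(cells):
        j = 0
        for f in scalars:
            data[i, j] = c.scalar_features[f.name]
            j += 1
        for f in dists:
            rec = summarize_distributed(
                c.distributed_features[f.name], count=(f.family == COUNT)
            )
            for s in STATISTICS:
                data[i, j] = rec[s]
                j += 1

    values = pd.DataFrame(data, index=[c.cell_id for c in cells], columns=columns)
    values.index.name = "cell_id"
    row_meta = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "mouse_id": [c.mouse_id for c in cells],
            "genotype": [c.genotype for c in cells],
            "time_days": [c.time_days for c in cells],
            "latent_state": [c.latent_state for c in cells],
            "n_processes": [c.n_processes for c in cells],
        }
    ).set_index("cell_id", drop=False)
    col_meta = pd.DataFrame([vars(d) | {} for d in col_meta_rows])
    return FeatureMatrix(values, row_meta, col_meta)


def zscore(fm: FeatureMatrix) -> FeatureMatrix:
    """Standardize each column to mean 0, unit sample (n-1) standard deviation.

    Constant columns carry no information and are dropped with a warning; an
    all-constant matrix is an error.
    """
    if fm.n_cells < 2:
        raise ValueError("z-scoring needs at least two cells")
    sd = fm.values.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant; nothing to standardize")
    if not keep.all():
        dropped = list(sd.index[~keep])
        warnings.warn(f"dropping {len(dropped)} constant column(s): {dropped}")
    vals = fm.values.loc[:, keep]
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    cm = fm.col_meta[fm.col_meta["name"].isin(z.columns)].reset_index(drop=True)
    return FeatureMatrix(z, fm.row_meta.copy(), cm)


def select_features(
    loadings: pd.DataFrame,
    odp_p: pd.Series,
    loading_cutoff: float = 0.2,
    alpha: float = 0.05,
    magnitude: str = "l2",
) -> list[str]:
    """Inclusive feature selection: large PCA loading OR significant dynamics.

    A feature is kept when its loading magnitude across the first four
    principal components exceeds ``loading_cutoff`` or its time-course test
    p-value falls below ``alpha``.  Magnitude is the Euclidean norm of the
    feature's loadings on components 1-4 by default (``magnitude="max"``
    switches to the maximum absolute loading); with orthonormal loadings the
    norm convention concentrates on features that support the leading
    components in any direction, which keeps the selected set near the
    expected size for this catalog (~65 of 110 columns).
    """
    if loadings.shape[1] < 4:
        raise ValueError("need loadings for at least four principal components")
    sub = loadings.iloc[:, :4]
    if magnitude == "max":
        mag = sub.abs().max(axis=1)
    elif magnitude == "l2":
        mag = np.sqrt((sub ** 2).sum(axis=1))
    else:
        raise ValueError(f"unknown magnitude convention: {magnitude!r}")
    p = odp_p.reindex(loadings.index)
    selected = (mag > loading_cutoff) | (p < alpha)
    return list(loadings.index[selected.fillna(False)])


def shift_nonnegative(fm: FeatureMatrix) -> pd.DataFrame:
    """Return the features x cells non-negative matrix D for factorization.

    Each feature (row of D) has its minimum subtracted, so every row attains
    exactly zero — including rows that were already non-negative.
    """
    vals = fm.values.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in feature matrix")
    D = fm.values.T.copy()
    D = D.sub(D.min(axis=1), axis=0)
    return D
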