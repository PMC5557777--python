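"""Time-course significance testing of morphological features.

For each feature we ask whether its temporal profile differs between
genotypes by comparing two least-squares natural-cubic-spline fits: a pooled
fit ignoring genotype (error SS0) and genotype-specific curves (error SSA).
The statistic

    F = (SS0 - SSA) / SSA

measures the relative gain of the genotype-specific model.  Its null
distribution is built by a residual bootstrap: residuals of the
genotype-specific (alternative) fit — pure noise even when a genotype effect
exists — are resampled with replacement (cells are the resampling unit,
genotype labels stay fixed) and added back to the pooled fitted values, and F
is recomputed for each resample.  The bootstrap p-value is

    p = (1 + #{F_null >= F_obs}) / (1 + n_boot),

adjusted across features to q-values — by default with Storey's
null-proportion-corrected estimator (the convention of time-course
significance software); plain Benjamini-Hochberg is available.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix

__all__ = [
    "natural_spline_basis",
    "fit_spline_sse",
    "odp_statistic",
    "bootstrap_null",
    "adjust_fdr",
    "ks_compare",
    "odp_test",
]

DEFAULT_DF = 3


def natural_spline_basis(times: np.ndarray, df: int = DEFAULT_DF) -> np.ndarray:
    """Intercept + natural cubic regression spline basis evaluated at ``times``."""
    import patsy

    times = np.asarray(times, dtype=float)
    n_distinct = np.unique(times).size
    if n_distinct < 2:
        raise ValueError("need at least two distinct time values")
    if df > n_distinct:
        raise ValueError(f"spline df={df} exceeds {n_distinct} distinct time values")
    X = patsy.dmatrix(f"cr(x, df={df})", {"x": times}, return_type="matrix")
    return np.asarray(X)


def _grouped_design(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Block design with one copy of the spline basis per group."""
    levels = pd.unique(groups)
    cols = []
    for lev in levels:
        mask = (groups == lev).astype(float)[:, None]
        cols.append(X * mask)
    return np.hstack(cols)


def _ortho(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    return U[:, s > tol]


def fit_spline_sse(
    values: Sequence[float],
    times: Sequence[float],
    groups: Optional[Sequence] = None,
    df: int = DEFAULT_DF,
) -> float:
    """Sum of squared error of the least-squares spline fit.

    With ``groups`` given, one curve is fitted per group and the SSE summed.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("values and times must have equal length")
    X = natural_spline_basis(t, df=df)
    if groups is not None:
        X = _grouped_design(X, np.asarray(groups))
    Q = _ortho(X)
    resid = y - Q @ (Q.T @ y)
    return float(resid @ resid)


def odp_statistic(SS0: float, SSA: float) -> float:
    """Relative goodness-of-fit gain F = (SS0 - SSA) / SSA."""
    if SSA < 0 or SS0 < 0:
        raise ValueError("sums of squares must be non-negative")
    if SSA == 0:
        warnings.warn("genotype-specific fit is exact (SSA = 0); F reported as inf")
        return float("inf")
    return (SS0 - SSA) / SSA


def bootstrap_null(
    Y: pd.DataFrame,
    times: Sequence[float],
    groups: Sequence,
    n_boot: int = 500,
    seed: int = 0,
    df: int = DEFAULT_DF,
) -> pd.DataFrame:
    """Per-feature observed F and residual-bootstrap p-values.

    ``Y`` is cells x features.  Null data are built as pooled-fit values plus
    residuals of the genotype-specific fit, resampled with replacement within
    each genotype-by-time stratum — one index draw shared across features per
    bootstrap replicate — while genotype labels and the time design stay
    fixed.  Alternative-model residuals keep genuine genotype signal out of
    the null, and stratified resampling preserves the group-specific
    dispersion (LPS visibly widens the distributions, so pooling residuals
    across groups would inflate the null tail).  Returns a DataFrame with
    SS0, SSA, F and p per feature.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    Ymat = Y.to_numpy(dtype=float)
    n = Ymat.shape[0]
    t = np.asarray(times, dtype=float)
    g = np.asarray(groups)
    X0 = natural_spline_basis(t, df=df)
    Q0 = _ortho(X0)
    Qa = _ortho(_grouped_design(X0, g))

    def _sse(Q: np.ndarray, M: np.ndarray) -> np.ndarray:
        R = M - Q @ (Q.T @ M)
        return np.einsum("ij,ij->j", R, R)

    ss0 = _sse(Q0, Ymat)
    ssa = _sse(Qa, Ymat)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = np.where(ssa > 0, (ss0 - ssa) / np.where(ssa > 0, ssa, 1.0), np.inf)

    # Alternative-model residuals; the pooled fitted values they are added to
    # lie in the column space of both designs, so they drop out of every SSE.
    resid_a = Ymat - Qa @ (Qa.T @ Ymat)
    strata = pd.Series(list(zip(g, t)))
    stratum_idx = [np.flatnonzero(strata == s) for s in strata.unique()]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(Ymat.shape[1], dtype=int)
    idx = np.empty(n, dtype=int)
    for _ in range(n_boot):
        for members in stratum_idx:
            idx[members] = rng.choice(members, size=members.size, replace=True)
        Rb = resid_a[idx]
        b0 = _sse(Q0, Rb)
        ba = _sse(Qa, Rb)
        with np.errstate(divide="ignore", invalid="ignore"):
            fb = np.where(ba > 0, (b0 - ba) / np.where(ba > 0, ba, 1.0), np.inf)
        exceed += fb >= f_obs
    p = (1.0 + exceed) / (1.0 + n_boot)
    return pd.DataFrame(
        {"SS0": ss0, "SSA": ssa, "F": f_obs, "p": p}, index=Y.columns
    )


def adjust_fdr(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """False-discovery-rate adjusted q-values (monotone in p)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    q_bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q_bh
    if method == "storey":
        # fixed-lambda (0.5) estimate of the null proportion
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if p.size else 1.0
        pi0 = max(pi0, 1.0 / p.size)
        return np.minimum(q_bh * pi0, 1.0)
    raise ValueError(f"unknown FDR method: {method!r}")


def ks_compare(dist_a: Sequence[float], dist_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test with asymptotic p-value.

    Ties are handled by the standard ECDF convention (jumps of multiplicity).
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def odp_test(
    fm: FeatureMatrix,
    n_boot: int = 500,
    seed: int = 0,
    df: int = DEFAULT_DF,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """Run the full per-feature time-course test on an assembled matrix.

    q-values default to the Storey estimator (the convention of time-course
    significance software): its null-proportion correction keeps the 5% FDR
    cut usable despite the granularity of bootstrap p-values (minimum 1 /
    (1 + n_boot)).  Pass ``fdr_method="bh"`` for plain Benjamini-Hochberg.
    """
    times = fm.row_meta["time_days"].to_numpy(dtype=float)
    groups = fm.row_meta["genotype"].to_numpy()
    res = bootstrap_null(fm.values, times, groups, n_boot=n_boot, seed=seed, df=df)
    res["q"] = adjust_fdr(res["p"].to_numpy(), method=fdr_method)
    res.index.name = "feature"
    return res
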