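"""Adaptive-recovery quantification of perturbed temporal profiles.

A feature *adapts* when, after the LPS-induced excursion, its level returns
toward the pre-stimulus baseline.  For each feature and genotype the per-time
mean Z-scores are min-max scaled to [0, 1] (the scaling span is taken over
the pooled wild-type + knockout time-point means so both genotypes share one
scale), profiles that respond by decreasing are flipped (Z -> 1 - Z, decided
by comparing the maximal deviations above and below baseline), and the
adaptation index is

    A = 1 - (Z_final - Z_t0) / (Z_peak - Z_t0),

so A = 1 means complete recovery and A = 0 no recovery.  The uncertainty of A
is propagated to first order from the standard errors of the peak and final
means (baseline treated as a constant):

    var(A) = SEM_final^2 (dA/dZ_final)^2 + SEM_peak^2 (dA/dZ_peak)^2.

Genotype contrasts use the pooled-spread T statistic

    T = (A_KO - A_WT) / sqrt(2 S^2 / n_min),
    S^2 = (n_min - 1)/df * (var_WT + var_KO),   df = 2 n_min - 2,

with n_min the smallest per-time sample count across both genotypes —
a deliberately conservative choice — and two-tailed p-values from the
t-distribution, Benjamini-Hochberg adjusted within each feature set.

A nonstandard convention is inherited from the reporting framework this
module follows: the "SEM" defaults to standard deviation divided by n (not
by sqrt(n)).  Pass ``sem_mode="sd_over_sqrt_n"`` for the textbook estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .odp import adjust_fdr

__all__ = [
    "ScaledProfile",
    "AdaptationEstimate",
    "AdaptationComparison",
    "FlatProfileError",
    "scale_and_orient",
    "adaptation_index",
    "adaptation_variance",
    "estimate_adaptation",
    "eligible_for_comparison",
    "compare_adaptation",
    "adaptation_table",
    "featureset_dynamics",
]

SEM_MODES = ("sd_over_n", "sd_over_sqrt_n")


class FlatProfileError(ValueError):
    """Profile with no excursion (max = min); excluded from adaptation."""


def _sem(values: np.ndarray, mode: str) -> float:
    n = values.size
    if n < 2:
        return 0.0
    sd = float(values.std(ddof=1))
    if mode == "sd_over_n":
        return sd / n
    if mode == "sd_over_sqrt_n":
        return sd / np.sqrt(n)
    raise ValueError(f"unknown SEM mode: {mode!r}")


@dataclass
class ScaledProfile:
    """Min-max scaled, orientation-corrected temporal profile of one feature."""

    feature: str
    genotype: str
    times: np.ndarray
    zbar: np.ndarray         # scaled (and possibly flipped) per-time means
    sem: np.ndarray          # per-time SEM on the scaled scale
    n_per_time: np.ndarray
    direction: str           # "increase" | "decrease" (pre-flip response sign)

    @property
    def n_min(self) -> int:
        return int(self.n_per_time.min())

    @property
    def peak_index(self) -> int:
        """Post-baseline extreme after orientation (largest scaled mean)."""
        return 1 + int(np.argmax(self.zbar[1:]))


def scale_and_orient(
    z_by_time: Mapping[float, Sequence[float]],
    feature: str = "",
    genotype: str = "",
    pooled_min: Optional[float] = None,
    pooled_max: Optional[float] = None,
    sem_mode: str = "sd_over_n",
) -> ScaledProfile:
    """Scale per-time Z values to [0, 1] and orient the response upward.

    ``pooled_min``/``pooled_max`` override the scaling span (used to put both
    genotypes of one feature on a shared scale); by default the span of this
    profile's own time-point means is used.  If the downward deviation from
    baseline exceeds the upward one, the profile is flipped (Z -> 1 - Z) and
    marked as a decreasing response.  SEMs are computed from the individual Z
    values transformed with the same scaling factors.
    """
    times = np.array(sorted(z_by_time), dtype=float)
    if times.size < 2:
        raise ValueError("need at least two timepoints including baseline")
    groups = [np.asarray(z_by_time[t], dtype=float) for t in times]
    means = np.array([g.mean() for g in groups])
    mn = float(means.min()) if pooled_min is None else float(pooled_min)
    mx = float(means.max()) if pooled_max is None else float(pooled_max)
    if mx <= mn:
        raise FlatProfileError(f"flat profile for {feature!r}/{genotype!r}: max == min")
    span = mx - mn
    zbar = (means - mn) / span
    sem = np.array([_sem((g - mn) / span, sem_mode) for g in groups])
    d_max = abs(zbar.max() - zbar[0])
    d_min = abs(zbar.min() - zbar[0])
    if d_min > d_max:
        zbar = 1.0 - zbar
        direction = "decrease"
    else:
        direction = "increase"
    return ScaledProfile(
        feature=feature,
        genotype=genotype,
        times=times,
        zbar=zbar,
        sem=sem,
        n_per_time=np.array([g.size for g in groups]),
        direction=direction,
    )


def adaptation_index(profile: ScaledProfile) -> float:
    """A = 1 - (Z_final - Z_t0) / (Z_peak - Z_t0); peak is the post-baseline extreme."""
    z0 = profile.zbar[0]
    z_final = profile.zbar[-1]
    z_peak = profile.zbar[profile.peak_index]
    if z_peak == z0:
        raise FlatProfileError(f"no excursion for {profile.feature!r}/{profile.genotype!r}")
    return float(1.0 - (z_final - z0) / (z_peak - z0))


def adaptation_variance(profile: ScaledProfile) -> float:
    """First-order propagated variance of A from the peak and final SEMs."""
    z0 = profile.zbar[0]
    pk = profile.peak_index
    z_peak = profile.zbar[pk]
    z_final = profile.zbar[-1]
    denom = z_peak - z0
    if denom == 0:
        raise FlatProfileError("zero peak-baseline span")
    dA_dfinal = -1.0 / denom
    dA_dpeak = (z_final - z0) / denom ** 2
    sem_final = profile.sem[-1]
    sem_peak = profile.sem[pk]
    return float(sem_final ** 2 * dA_dfinal ** 2 + sem_peak ** 2 * dA_dpeak ** 2)


@dataclass
class AdaptationEstimate:
    feature: str
    genotype: str
    A: float
    var_A: float
    ci95: tuple[float, float]
    n_min: int
    direction: str


def estimate_adaptation(profile: ScaledProfile) -> AdaptationEstimate:
    A = adaptation_index(profile)
    var_A = adaptation_variance(profile)
    n_min = profile.n_min
    df = max(2 * n_min - 2, 1)
    half = float(stats.t.ppf(0.975, df) * np.sqrt(var_A) / np.sqrt(n_min))
    return AdaptationEstimate(
        feature=profile.feature,
        genotype=profile.genotype,
        A=A,
        var_A=var_A,
        ci95=(A - half, A + half),
        n_min=n_min,
        direction=profile.direction,
    )


def eligible_for_comparison(
    A_wt: float,
    A_ko: float,
    direction_wt: str = "increase",
    direction_ko: str = "increase",
    min_adaptation: float = 0.5,
    lower: float = -0.2,
    upper: float = 1.2,
) -> bool:
    """Inclusion rule for genotype contrasts of the adaptation index.

    Both genotypes must respond in the same direction, both indices must lie
    inside (lower, upper), and the weaker of the two must exceed
    ``min_adaptation``.
    """
    if direction_wt != direction_ko:
        return False
    return (
        min(A_wt, A_ko) > min_adaptation
        and lower < A_wt < upper
        and lower < A_ko < upper
    )


@dataclass
class AdaptationComparison:
    feature: str
    A_WT: float
    A_KO: float
    T: float
    S2: float
    df: int
    p: float
    q: float = np.nan


def compare_adaptation(
    A_wt: float,
    A_ko: float,
    var_wt: float,
    var_ko: float,
    n_min: int,
    feature: str = "",
) -> AdaptationComparison:
    """Pooled-spread t-type contrast of the two genotypes' adaptation indices."""
    if n_min < 2:
        raise ValueError("n_min must be at least 2")
    df = 2 * n_min - 2
    S2 = (n_min - 1) / df * (var_wt + var_ko)
    if A_ko == A_wt:
        T = 0.0
    elif S2 == 0:
        T = np.inf if A_ko > A_wt else -np.inf
    else:
        T = (A_ko - A_wt) / np.sqrt(2.0 * S2 / n_min)
    p = float(2.0 * stats.t.sf(abs(T), df)) if np.isfinite(T) else 0.0
    if T == 0.0:
        p = 1.0
    return AdaptationComparison(feature, A_wt, A_ko, float(T), float(S2), df, p)


# ---------------------------------------------------------------------------
# Matrix-level drivers
# ---------------------------------------------------------------------------

def _profiles_for_feature(
    zfm: FeatureMatrix, feature: str, sem_mode: str
) -> dict[str, ScaledProfile]:
    """Pooled-scale, per-genotype profiles of one z-scored feature column."""
    col = zfm.values[feature]
    meta = zfm.row_meta
    by_gt: dict[str, dict[float, np.ndarray]] = {}
    means = []
    for gt in pd.unique(meta["genotype"]):
        sel = meta["genotype"] == gt
        z_by_time = {
            float(t): col[sel & (meta["time_days"] == t)].to_numpy()
            for t in sorted(meta.loc[sel, "time_days"].unique())
        }
        by_gt[gt] = z_by_time
        means.extend(v.mean() for v in z_by_time.values())
    mn, mx = float(np.min(means)), float(np.max(means))
    return {
        gt: scale_and_orient(
            z_by_time, feature=feature, genotype=gt,
            pooled_min=mn, pooled_max=mx, sem_mode=sem_mode,
        )
        for gt, z_by_time in by_gt.items()
    }


def adaptation_table(
    zfm: FeatureMatrix,
    features: Optional[Sequence[str]] = None,
    sem_mode: str = "sd_over_n",
    wt_label: str = "WT",
    ko_label: str = "KO",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adaptation indices and eligible genotype comparisons for many features.

    Returns ``(indices, comparisons)``: per-feature, per-genotype estimates
    with confidence intervals, and the T-statistic table for features passing
    the eligibility rule, with Benjamini-Hochberg q-values computed within
    each feature set.
    """
    cols = list(features) if features is not None else list(zfm.values.columns)
    fset = zfm.col_meta.set_index("name")["feature_set"]
    idx_rows, cmp_rows = [], []
    for feature in cols:
        try:
            profs = _profiles_for_feature(zfm, feature, sem_mode)
            est = {gt: estimate_adaptation(p) for gt, p in profs.items()}
        except FlatProfileError:
            continue
        for gt, e in est.items():
            idx_rows.append(
                {
                    "feature": feature,
                    "feature_set": fset.get(feature, "unassigned"),
                    "genotype": gt,
                    "A": e.A,
                    "var_A": e.var_A,
                    "ci95_lo": e.ci95[0],
                    "ci95_hi": e.ci95[1],
                    "n_min": e.n_min,
                    "direction": e.direction,
                }
            )
        if wt_label in est and ko_label in est:
            ew, ek = est[wt_label], est[ko_label]
            if eligible_for_comparison(ew.A, ek.A, ew.direction, ek.direction):
                n_min = min(ew.n_min, ek.n_min)
                c = compare_adaptation(ew.A, ek.A, ew.var_A, ek.var_A, n_min, feature)
                cmp_rows.append(
                    {
                        "feature": feature,
                        "feature_set": fset.get(feature, "unassigned"),
                        "A_WT": c.A_WT,
                        "A_KO": c.A_KO,
                        "T": c.T,
                        "df": c.df,
                        "p": c.p,
                    }
                )
    indices = pd.DataFrame(idx_rows)
    comparisons = pd.DataFrame(cmp_rows)
    if not comparisons.empty:
        comparisons["q"] = np.nan
        for fs, grp in comparisons.groupby("feature_set"):
            comparisons.loc[grp.index, "q"] = adjust_fdr(grp["p"].to_numpy())
    return indices, comparisons


def featureset_dynamics(
    zfm: FeatureMatrix,
    feature_sets: Optional[pd.Series] = None,
    sidak_family: Optional[int] = None,
) -> dict[str, dict]:
    """Per-set mean dynamics with two-way ANOVA and LSD/Sidak post-hocs.

    For each feature set, cells are summarized by the mean Z-score over the
    member features and analyzed with a genotype x time two-way ANOVA.  The
    post-hoc family comprises the within-genotype comparisons of every later
    time point against baseline and the between-genotype comparison at each
    time point, each a Fisher LSD t-test on the pooled residual variance with
    a Sidak correction over the family.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    meta = zfm.row_meta
    if feature_sets is None:
        feature_sets = zfm.col_meta.set_index("name")["feature_set"]
    out: dict[str, dict] = {}
    for fs in sorted(set(feature_sets) - {"unassigned"}):
        members = feature_sets.index[feature_sets == fs]
        members = [m for m in members if m in zfm.values.columns]
        if not members:
            continue
        y = zfm.values[members].mean(axis=1)
        df_fit = pd.DataFrame(
            {
                "y": y.to_numpy(),
                "genotype": meta["genotype"].to_numpy(),
                "time": meta["time_days"].astype(float).to_numpy(),
            }
        )
        if df_fit.groupby(["genotype", "time"]).size().min() < 1:
            raise ValueError(f"empty design cell for feature set {fs}")
        model = smf.ols("y ~ C(genotype) * C(time)", data=df_fit).fit()
        anova = anova_lm(model, typ=2)
        mse = model.mse_resid
        dof = int(model.df_resid)
        summary = (
            df_fit.groupby(["genotype", "time"])["y"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
            .reset_index()
        )
        summary["sem"] = summary["sd"] / np.sqrt(summary["n"])

        cellstats = summary.set_index(["genotype", "time"])
        times = sorted(df_fit["time"].unique())
        genotypes = list(pd.unique(df_fit["genotype"]))
        comparisons = []
        for gt in genotypes:
            for t in times[1:]:
                comparisons.append(((gt, times[0]), (gt, t), f"{gt}: t0 vs t{t:g}"))
        if len(genotypes) == 2:
            g1, g2 = genotypes
            for t in times:
                comparisons.append(((g1, t), (g2, t), f"{g1} vs {g2} at t{t:g}"))
        m = sidak_family if sidak_family is not None else len(comparisons)
        rows = []
        for a, b, label in comparisons:
            ma, na = cellstats.loc[a, "mean"], cellstats.loc[a, "n"]
            mb, nb = cellstats.loc[b, "mean"], cellstats.loc[b, "n"]
            se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
            tstat = (mb - ma) / se if se > 0 else 0.0
            p = float(2.0 * stats.t.sf(abs(tstat), dof))
            p_sidak = float(1.0 - (1.0 - p) ** m) if p < 1 else 1.0
            rows.append({"comparison": label, "t": float(tstat), "p": p, "p_sidak": min(p_sidak, 1.0)})
        out[fs] = {
            "summary": summary,
            "anova": anova,
            "posthoc": pd.DataFrame(rows),
        }
    return out
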