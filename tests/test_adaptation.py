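"""Adaptation index, propagated uncertainty, eligibility and genotype contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from gliamorph.adaptation import (
    FlatProfileError,
    ScaledProfile,
    adaptation_index,
    adaptation_table,
    adaptation_variance,
    compare_adaptation,
    eligible_for_comparison,
    estimate_adaptation,
    featureset_dynamics,
    scale_and_orient,
)

TIMES = (0.0, 1.0, 3.0, 5.0)


def _profile_from_means(means, sems=None, times=TIMES, direction="increase"):
    means = np.asarray(means, dtype=float)
    sems = np.zeros_like(means) if sems is None else np.asarray(sems, dtype=float)
    return ScaledProfile(
        feature="f", genotype="WT", times=np.asarray(times, float),
        zbar=means, sem=sems, n_per_time=np.full(means.size, 20), direction=direction,
    )


def _groups(means, n=30, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return {t: rng.normal(m, sd, n) for t, m in zip(TIMES, means)}


class TestScaleAndOrient:
    def test_min_max_arithmetic(self):
        prof = scale_and_orient({t: [m] * 3 for t, m in zip(TIMES, (0.1, 0.9, 0.5, 0.2))})
        assert prof.zbar == pytest.approx([0.0, 1.0, 0.5, 0.125])
        assert prof.direction == "increase"

    def test_downward_response_is_flipped(self):
        prof = scale_and_orient({t: [m] * 3 for t, m in zip(TIMES, (0.9, 0.1, 0.5, 0.8))})
        assert prof.direction == "decrease"
        # after flipping, the day-1 trough becomes the peak
        assert prof.zbar[1] == pytest.approx(1.0)
        assert prof.peak_index == 1

    def test_sem_scales_with_the_same_factors(self):
        groups = _groups((0.0, 2.0, 1.0, 0.4), sd=0.8, seed=3)
        raw_span = max(np.mean(v) for v in groups.values()) - min(
            np.mean(v) for v in groups.values()
        )
        prof = scale_and_orient(groups)
        for i, t in enumerate(TIMES):
            v = np.asarray(groups[t])
            raw_sem = v.std(ddof=1) / v.size  # documented sd/n convention
            assert prof.sem[i] == pytest.approx(raw_sem / raw_span)

    def test_textbook_sem_available(self):
        groups = _groups((0.0, 2.0, 1.0, 0.4), sd=0.8, seed=4)
        prof = scale_and_orient(groups, sem_mode="sd_over_sqrt_n")
        v = np.asarray(groups[0.0])
        span = max(np.mean(g) for g in groups.values()) - min(
            np.mean(g) for g in groups.values()
        )
        assert prof.sem[0] == pytest.approx(v.std(ddof=1) / np.sqrt(v.size) / span)

    def test_flat_profile_is_flagged(self):
        with pytest.raises(FlatProfileError):
            scale_and_orient({t: [1.0, 1.0] for t in TIMES})


class TestAdaptationIndex:
    def test_complete_recovery(self):
        assert adaptation_index(_profile_from_means([0.0, 1.0, 0.4, 0.0])) == 1.0

    def test_no_recovery(self):
        assert adaptation_index(_profile_from_means([0.0, 0.5, 1.0, 1.0])) == 0.0

    def test_direct_substitution(self):
        assert adaptation_index(_profile_from_means([0.0, 1.0, 0.5, 0.25])) == 0.75

    def test_affine_invariance_of_raw_profile(self):
        """A is unchanged when the raw per-cell values are affinely rescaled."""
        groups = _groups((0.0, 2.0, 1.0, 0.5), seed=5)
        scaled = {t: 3.5 * np.asarray(v) - 7.0 for t, v in groups.items()}
        a1 = adaptation_index(scale_and_orient(groups))
        a2 = adaptation_index(scale_and_orient(scaled))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_no_excursion_is_an_error(self):
        with pytest.raises(FlatProfileError):
            adaptation_index(_profile_from_means([0.5, 0.5, 0.5, 0.5]))


class TestAdaptationVariance:
    def test_zero_sems_give_zero_variance(self):
        prof = _profile_from_means([0.0, 1.0, 0.6, 0.2])
        assert adaptation_variance(prof) == 0.0

    def test_unit_final_sensitivity(self):
        """With baseline 0 and peak 1, dA/dZ_final = -1, so var = SEM_final^2."""
        prof = _profile_from_means([0.0, 1.0, 0.8, 0.5], sems=[0.0, 0.0, 0.0, 0.1])
        assert adaptation_variance(prof) == pytest.approx(0.01)

    def test_matches_monte_carlo_propagation(self):
        """First-order propagation tracks direct simulation within 5%."""
        base, peak, final = 0.0, 1.0, 0.35
        sem_peak, sem_final = 0.04, 0.05
        prof = _profile_from_means([base, peak, 0.7, final],
                                   sems=[0.0, sem_peak, 0.0, sem_final])
        var_analytic = adaptation_variance(prof)
        rng = np.random.default_rng(8)
        zp = rng.normal(peak, sem_peak, 100_000)
        zf = rng.normal(final, sem_final, 100_000)
        A = 1.0 - (zf - base) / (zp - base)
        assert var_analytic == pytest.approx(A.var(), rel=0.05)

    def test_confidence_interval_symmetric(self):
        prof = _profile_from_means([0.0, 1.0, 0.8, 0.3],
                                   sems=[0.0, 0.05, 0.0, 0.05])
        est = estimate_adaptation(prof)
        lo, hi = est.ci95
        assert (lo + hi) / 2 == pytest.approx(est.A)
        assert est.var_A >= 0


class TestEligibility:
    @pytest.mark.parametrize(
        "a_wt,a_ko,d_wt,d_ko,expected",
        [
            (0.8, 0.9, "increase", "increase", True),
            (0.4, 0.9, "increase", "increase", False),   # weak WT adaptation
            (1.3, 0.9, "increase", "increase", False),   # out of range
            (0.8, -0.3, "increase", "increase", False),
            (0.8, 0.9, "increase", "decrease", False),   # direction mismatch
        ],
    )
    def test_threshold_rules(self, a_wt, a_ko, d_wt, d_ko, expected):
        assert eligible_for_comparison(a_wt, a_ko, d_wt, d_ko) is expected


class TestCompareAdaptation:
    def test_equal_indices_give_null_result(self):
        c = compare_adaptation(0.8, 0.8, 0.01, 0.01, n_min=20)
        assert c.T == 0.0 and c.p == 1.0
        assert c.df == 38

    def test_vanishing_variance_limit(self):
        c = compare_adaptation(0.6, 0.9, 1e-12, 1e-12, n_min=20)
        assert c.p < 1e-10

    def test_pvalue_matches_density_quadrature(self):
        c = compare_adaptation(0.6, 0.8, 0.004, 0.006, n_min=15)
        df = 2 * 15 - 2
        tail, _ = quad(lambda x: stats.t.pdf(x, df), abs(c.T), np.inf)
        assert c.p == pytest.approx(2 * tail, rel=1e-6)

    def test_statistic_follows_pooled_spread_formula(self):
        a_wt, a_ko, v_wt, v_ko, n = 0.55, 0.92, 0.003, 0.005, 12
        c = compare_adaptation(a_wt, a_ko, v_wt, v_ko, n)
        S2 = (n - 1) / (2 * n - 2) * (v_wt + v_ko)
        assert c.T == pytest.approx((a_ko - a_wt) / np.sqrt(2 * S2 / n))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_adaptation(0.6, 0.8, 0.01, 0.01, n_min=1)


class TestOnSyntheticStudy:
    def test_planted_soma_features_adapt_more_in_knockout(self, selected_matrix):
        """The designed fs2 contrast: knockout recovery beats wild type."""
        _, comparisons = adaptation_table(selected_matrix)
        fs2 = comparisons[comparisons.feature_set == "fs2"]
        assert len(fs2) > 0
        hits = (fs2.A_KO > fs2.A_WT) & (fs2.q < 0.05)
        assert hits.mean() > 0.5

    def test_indices_carry_uncertainty(self, selected_matrix):
        indices, _ = adaptation_table(selected_matrix)
        assert (indices.var_A >= 0).all()
        assert (indices.ci95_hi >= indices.ci95_lo).all()
        assert set(indices.genotype) == {"WT", "KO"}


class TestFeaturesetDynamics:
    def test_identical_groups_show_no_posthoc_differences(self):
        rng = np.random.default_rng(9)
        from gliamorph.features import FeatureMatrix

        n = 160
        vals = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)},
                            index=[f"c{i}" for i in range(n)])
        row_meta = pd.DataFrame(
            {
                "cell_id": vals.index,
                "mouse_id": "m01",
                "genotype": np.repeat(["WT", "KO"], n // 2),
                "time_days": np.tile(np.repeat(TIMES, n // 8), 2).astype(float),
            }
        ).set_index("cell_id", drop=False)
        col_meta = pd.DataFrame(
            {"name": ["a", "b"], "base_feature": ["a", "b"], "compartment": "soma",
             "distributed": False, "statistic": "none", "feature_set": "fs2"}
        )
        fm = FeatureMatrix(vals, row_meta, col_meta)
        out = featureset_dynamics(fm)
        post = out["fs2"]["posthoc"]
        assert (post.p_sidak > 0.05).mean() > 0.8  # no systematic differences

    def test_anova_f_matches_textbook_formula(self):
        """Balanced two-group genotype effect: F equals the hand-computed ratio."""
        from gliamorph.features import FeatureMatrix

        rng = np.random.default_rng(10)
        n = 80
        genotype = np.repeat(["WT", "KO"], n // 2)
        time = np.tile(np.repeat([0.0, 1.0], n // 4), 2)
        y = rng.normal(size=n) + (genotype == "KO") * 0.8
        vals = pd.DataFrame({"a": y}, index=[f"c{i}" for i in range(n)])
        row_meta = pd.DataFrame(
            {"cell_id": vals.index, "mouse_id": "m01",
             "genotype": genotype, "time_days": time}
        ).set_index("cell_id", drop=False)
        col_meta = pd.DataFrame(
            {"name": ["a"], "base_feature": ["a"], "compartment": "soma",
             "distributed": False, "statistic": "none", "feature_set": "fs2"}
        )
        out = featureset_dynamics(FeatureMatrix(vals, row_meta, col_meta))
        anova = out["fs2"]["anova"]
        # hand-computed genotype F for the balanced design: marginal-mean sum
        # of squares over the full-model residual mean square
        df = pd.DataFrame({"y": y, "g": genotype, "t": time})
        grand = df["y"].mean()
        ss_g = sum(
            (n // 2) * (df[df.g == g]["y"].mean() - grand) ** 2
            for g in ("WT", "KO")
        )
        cell = df.groupby(["g", "t"])["y"].transform("mean")
        ms_resid = ((df["y"] - cell) ** 2).sum() / (n - 4)
        f_hand = ss_g / ms_resid
        assert anova.loc["C(genotype)", "F"] == pytest.approx(f_hand, rel=1e-6)

    def test_planted_interaction_detected(self, selected_matrix):
        out = featureset_dynamics(selected_matrix)
        inter_p = out["fs2"]["anova"].loc["C(genotype):C(time)", "PR(>F)"]
        assert inter_p < 0.001
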