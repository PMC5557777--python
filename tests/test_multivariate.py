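"""PCA, offset-NMF, feature sets, rank-correlation distance, NMDS, enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from gliamorph import synthetic as syn
from gliamorph.features import (
    build_feature_matrix,
    select_features,
    shift_nonnegative,
    zscore,
)
from gliamorph.multivariate import (
    assign_feature_sets,
    cluster_enrichment,
    nmds,
    nmf,
    pca,
    rank_survey,
    spearman_distance,
)
from gliamorph.odp import odp_test


class TestPca:
    def test_perfectly_correlated_pair_loads_one_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        res = pca(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, pca_results):
        L = pca_results.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_scores_equal_projection_oracle(self, zmatrix, pca_results):
        X = zmatrix.values.to_numpy()
        Xc = X - X.mean(axis=0)
        proj = Xc @ pca_results.loadings.to_numpy()
        assert np.allclose(proj, pca_results.scores.to_numpy(), atol=1e-8)

    def test_variance_fractions_sum_to_one(self, pca_results):
        assert pca_results.variance_fraction.sum() == pytest.approx(1.0)

    def test_sign_convention(self, pca_results):
        L = pca_results.loadings.to_numpy()
        peaks = L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])]
        assert (peaks > 0).all()


class TestNmf:
    def test_recovers_planted_rank_two_product(self):
        rng = np.random.default_rng(1)
        W = rng.random((30, 2))
        H = rng.random((2, 40))
        D = pd.DataFrame(W @ H)
        dec = nmf(D, rank=2, seed=0, max_iter=20000, tol=0.0)
        assert dec.reconstruction_error < 1e-3

    def test_constant_matrix_absorbed_by_offset_at_rank_one(self):
        D = pd.DataFrame(np.full((10, 12), 3.0))
        dec = nmf(D, rank=1, seed=0)
        assert dec.reconstruction_error < 1e-6

    def test_error_sequence_non_increasing(self, nmf_decomposition):
        hist = np.array(nmf_decomposition.error_history)
        assert (np.diff(hist) <= 1e-10).all()

    def test_factors_non_negative(self, nmf_decomposition):
        assert (nmf_decomposition.W.to_numpy() >= 0).all()
        assert (nmf_decomposition.H.to_numpy() >= 0).all()
        assert (nmf_decomposition.offset.to_numpy() >= 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nmf(pd.DataFrame([[1.0, -0.1]]), rank=1)

    def test_excessive_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            nmf(pd.DataFrame(np.ones((3, 3))), rank=5)

    def test_clusters_are_argmax_of_coefficients(self, nmf_decomposition):
        H = nmf_decomposition.H.to_numpy()
        assert (nmf_decomposition.cell_clusters.to_numpy()
                == np.argmax(H, axis=0) + 1).all()


class TestRankSurvey:
    def test_error_non_increasing_in_rank(self):
        rng = np.random.default_rng(2)
        W = rng.random((25, 3))
        H = rng.random((3, 30))
        D = pd.DataFrame(W @ H + 0.01 * rng.random((25, 30)))
        survey = rank_survey(D, ranks=(1, 2, 3, 4), seeds=(0, 1),
                             max_iter=800, tol=1e-9)
        assert (np.diff(survey.error.to_numpy()) <= 1e-6).all()

    def test_needs_two_seeds(self):
        with pytest.raises(ValueError):
            rank_survey(pd.DataFrame(np.ones((4, 4))), ranks=(1,), seeds=(0,))


class TestAssignFeatureSets:
    def _block_W(self, perm=None):
        W = np.zeros((12, 4))
        for b in range(4):
            W[3 * b: 3 * b + 3, b] = 1.0 + 0.05 * np.arange(3)
        if perm is not None:
            W = W[perm]
        return pd.DataFrame(W, index=[f"f{i}" for i in range(12)])

    def test_orthogonal_row_blocks_recovered_exactly(self):
        labels = assign_feature_sets(self._block_W())
        truth = np.repeat(np.arange(4), 3)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        assert labels.nunique() == 4

    def test_invariant_to_feature_order(self):
        rng = np.random.default_rng(3)
        perm = rng.permutation(12)
        base = assign_feature_sets(self._block_W()).to_numpy()
        shuffled = assign_feature_sets(self._block_W(perm)).to_numpy()
        assert adjusted_rand_score(base[perm], shuffled) == 1.0

    def test_all_zero_row_is_unassigned(self):
        W = self._block_W()
        W.iloc[0] = 0.0
        labels = assign_feature_sets(W)
        assert labels.iloc[0] == "unassigned"

    def test_four_planted_blocks_recovered_from_synthetic_study(self):
        """Block-structured data: the W-row tree cut matches the four sets."""
        cfg = syn.block_structured_config()
        cells = syn.generate_cells(syn.default_design(0), cfg)
        z = zscore(build_feature_matrix(cells))
        odp = odp_test(z, n_boot=500, seed=0)
        sel = select_features(pca(z).loadings, odp["p"])
        zsel = z.subset(sel)
        dec = nmf(shift_nonnegative(zsel), rank=4, seed=0)
        found = assign_feature_sets(dec.W, dec.H)
        meta = zsel.col_meta.set_index("name")
        truth = np.array([meta.loc[c, "feature_set"] for c in zsel.values.columns])
        keep = (found != "unassigned").to_numpy()
        assert found[keep].nunique() == 4
        assert adjusted_rand_score(truth[keep], found.to_numpy()[keep]) > 0.8


class TestSpearmanDistance:
    def test_self_distance_zero(self, selected_matrix):
        d = spearman_distance(selected_matrix.values.iloc[:15])
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert (d.to_numpy() >= -1e-12).all() and (d.to_numpy() <= 2 + 1e-12).all()

    def test_anti_monotone_profiles(self):
        Z = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [8.0, 6.0, 4.0, 2.0]],
                         index=["up", "down"])
        d = spearman_distance(Z)
        assert d.loc["up", "down"] == pytest.approx(2.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        Z = pd.DataFrame(rng.normal(size=(6, 20)))
        d = spearman_distance(Z)
        for i, j in itertools.combinations(range(6), 2):
            rho = stats.pearsonr(
                stats.rankdata(Z.iloc[i]), stats.rankdata(Z.iloc[j])
            ).statistic
            assert d.iloc[i, j] == pytest.approx(1 - rho, abs=1e-10)

    def test_constant_profile_names_offender(self):
        Z = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            spearman_distance(Z)


class TestNmds:
    def test_euclidean_configuration_embeds_with_low_stress(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        d = pd.DataFrame(squareform(pdist(X)))
        coords, stress = nmds(d, dims=3, seed=0)
        assert stress < 0.01
        assert coords.shape == (30, 3)

    def test_three_dimensions_fit_at_least_as_well_as_two(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 5))
        d = pd.DataFrame(squareform(pdist(X)))
        _, s3 = nmds(d, dims=3, seed=0)
        _, s2 = nmds(d, dims=2, seed=0)
        assert s3 <= s2 + 1e-6

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame(np.arange(9.0).reshape(3, 3))
        with pytest.raises(ValueError):
            nmds(bad)

    def test_planted_clusters_stay_compact(self, selected_matrix, nmf_decomposition):
        d = spearman_distance(selected_matrix)
        coords, _ = nmds(d, dims=3, seed=0, n_restarts=2)
        labels = nmf_decomposition.cell_clusters
        X = coords.to_numpy()
        within, between = [], []
        for a, b in itertools.combinations(range(len(labels)), 2):
            dist = np.linalg.norm(X[a] - X[b])
            (within if labels.iloc[a] == labels.iloc[b] else between).append(dist)
        assert np.mean(within) < np.mean(between)


class TestClusterEnrichment:
    def test_matches_exhaustive_enumeration(self):
        """Cluster of 5 all-knockout cells out of 20 (10 KO) total."""
        clusters = [1] * 5 + [2] * 15
        genotypes = ["KO"] * 5 + ["KO"] * 5 + ["WT"] * 10
        res = cluster_enrichment(clusters, genotypes)
        exact = comb(10, 5) / comb(20, 5)  # all draws that are entirely KO
        row = res[res.cluster == 1].iloc[0]
        assert row.p == pytest.approx(exact)
        assert exact == pytest.approx(0.016254, abs=1e-6)

    def test_whole_population_cluster_is_null(self):
        res = cluster_enrichment([1] * 12, ["KO"] * 6 + ["WT"] * 6)
        assert res.p.iloc[0] == pytest.approx(1.0)

    def test_planted_knockout_state_detected(self, nmf_decomposition, selected_matrix):
        res = cluster_enrichment(
            nmf_decomposition.cell_clusters,
            selected_matrix.row_meta["genotype"].to_numpy(),
        )
        assert res.p.min() < 0.05

    def test_six_clusters_non_empty_with_high_state_recovery(
        self, nmf_decomposition, selected_matrix
    ):
        clusters = nmf_decomposition.cell_clusters
        assert clusters.nunique() == 6
        ari = adjusted_rand_score(
            selected_matrix.row_meta["latent_state"].to_numpy(), clusters.to_numpy()
        )
        assert ari >= 0.7
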