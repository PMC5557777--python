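"""Shared fixtures: one default synthetic study analyzed once per session."""

import pytest

from gliamorph import synthetic as syn
from gliamorph.features import (
    build_feature_matrix,
    select_features,
    shift_nonnegative,
    zscore,
)
from gliamorph.multivariate import nmf, pca
from gliamorph.odp import odp_test

SEED = 0


@pytest.fixture(scope="session")
def default_cells():
    return syn.generate_cells(syn.default_design(SEED))


@pytest.fixture(scope="session")
def zmatrix(default_cells):
    return zscore(build_feature_matrix(default_cells))


@pytest.fixture(scope="session")
def odp_results(zmatrix):
    return odp_test(zmatrix, n_boot=500, seed=SEED)


@pytest.fixture(scope="session")
def pca_results(zmatrix):
    return pca(zmatrix)


@pytest.fixture(scope="session")
def selected_matrix(zmatrix, pca_results, odp_results):
    cols = select_features(pca_results.loadings, odp_results["p"])
    return zmatrix.subset(cols)


@pytest.fixture(scope="session")
def nmf_decomposition(selected_matrix):
    return nmf(shift_nonnegative(selected_matrix), rank=6, seed=SEED)
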