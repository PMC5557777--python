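"""Unsupervised multivariate analysis of the morphology matrix.

Three complementary views of the cells x features data:

* **PCA** for variance-driven feature screening (loadings over the first four
  components feed the selection rule).
* **Offset non-negative matrix factorization**: the non-negative data matrix
  D (features x cells) is approximated as W H + c 1', where the per-feature
  offset column c absorbs features expressed at constant levels across cells.
  W and H are initialized by NNDSVD (negative parts of the truncated SVD
  zeroed, zeros filled with a mean-scaled epsilon so multiplicative updates
  cannot get stuck at zero) and refined by multiplicative updates that
  minimize the squared reconstruction error.  Cells are assigned to the
  meta-feature with the largest coefficient; feature sets are read off W by
  hierarchical clustering of its normalized rows.
* **Nonmetric MDS** on the Spearman-correlation distance d = 1 - rho between
  cells, as an independent, rank-based validation of the NMF cell classes.

Cluster-genotype composition is scored with an upper-tail hypergeometric test
for knockout overrepresentation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.manifold import smacof
from sklearn.metrics import adjusted_rand_score, silhouette_score

__all__ = [
    "PCAResult",
    "NMFDecomposition",
    "pca",
    "nmf",
    "rank_survey",
    "assign_feature_sets",
    "spearman_distance",
    "nmds",
    "cluster_enrichment",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame        # cells x components
    loadings: pd.DataFrame      # features x components (orthonormal columns)
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca(Z) -> PCAResult:
    """Principal components of a cells x features matrix via SVD.

    Columns are centered internally.  Loadings are orthonormal; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    Components beyond the numeric rank are truncated with a warning.
    """
    values = Z.values if hasattr(Z, "values") and isinstance(Z.values, pd.DataFrame) else Z
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.asarray(values, dtype=float))
    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < min(Xc.shape[1], Xc.shape[0] - 1):
        warnings.warn(f"matrix has numeric rank {rank}; truncating components")
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    # sign convention: largest-magnitude loading positive per component
    signs = np.sign(Vt[np.arange(rank), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    var = s ** 2
    comp_names = [f"PC{i + 1}" for i in range(rank)]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=values.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=values.columns, columns=comp_names),
        variance_fraction=var / var.sum(),
    )


# ---------------------------------------------------------------------------
# Offset NMF
# ---------------------------------------------------------------------------

@dataclass
class NMFDecomposition:
    W: pd.DataFrame                 # features x rank basis
    H: pd.DataFrame                 # rank x cells coefficients
    offset: pd.Series               # per-feature constant
    rank: int
    reconstruction_error: float
    error_history: list[float] = field(default_factory=list)
    cell_clusters: pd.Series = None  # per-cell argmax meta-feature (1-based)
    feature_sets: pd.Series = None   # filled by assign_feature_sets

    def reconstruct(self) -> pd.DataFrame:
        rec = self.W.to_numpy() @ self.H.to_numpy() + self.offset.to_numpy()[:, None]
        return pd.DataFrame(rec, index=self.W.index, columns=self.H.columns)


def _nndsvd(D: np.ndarray, rank: int, rng: np.random.Generator):
    """NNDSVD initialization with mean-based zero fill."""
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    m, n = D.shape
    W = np.zeros((m, rank))
    H = np.zeros((rank, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, rank):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        nup, nun, nvp, nvn = map(np.linalg.norm, (up, un, vp, vn))
        if nup * nvp >= nun * nvn:
            scale, uu, vv = nup * nvp, up / max(nup, _EPS), vp / max(nvp, _EPS)
        else:
            scale, uu, vv = nun * nvn, un / max(nun, _EPS), vn / max(nvn, _EPS)
        W[:, j] = np.sqrt(S[j] * scale) * uu
        H[j, :] = np.sqrt(S[j] * scale) * vv
    # mean-based fill so multiplicative updates cannot lock entries at zero
    fill = max(D.mean() / 100.0, _EPS)
    W[W <= 0] = fill * (1.0 + 0.01 * rng.standard_normal(np.sum(W <= 0)))
    H[H <= 0] = fill * (1.0 + 0.01 * rng.standard_normal(np.sum(H <= 0)))
    return np.abs(W), np.abs(H)


def nmf(
    D,
    rank: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-7,
    init: str = "nndsvd",
) -> NMFDecomposition:
    """Offset non-negative factorization D ~ W H + c 1'.

    Multiplicative updates minimize the Frobenius reconstruction error; the
    offset column c is updated by the same rule (it behaves as an extra basis
    column whose coefficient row is fixed at one), so the error sequence is
    non-increasing.  Iteration stops when the relative error change drops
    below ``tol`` or after ``max_iter`` sweeps.
    """
    Dm = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, dtype=float)
    if np.any(Dm < 0):
        raise ValueError("NMF input must be non-negative")
    m, n = Dm.shape
    if not (1 <= rank <= min(m, n)):
        raise ValueError(f"rank must lie in [1, {min(m, n)}]")
    rng = np.random.default_rng(seed)
    if init == "nndsvd":
        W, H = _nndsvd(Dm, rank, rng)
    elif init == "random":
        scale = np.sqrt(Dm.mean() / rank)
        W = scale * rng.random((m, rank)) + _EPS
        H = scale * rng.random((rank, n)) + _EPS
    else:
        raise ValueError(f"unknown init: {init!r}")
    c = np.maximum(Dm.mean(axis=1) * 0.1, _EPS)

    norm_D = np.linalg.norm(Dm)
    history: list[float] = []
    prev = None
    for _ in range(max_iter):
        R = W @ H + c[:, None]
        H *= (W.T @ Dm) / np.maximum(W.T @ R, _EPS)
        R = W @ H + c[:, None]
        W *= (Dm @ H.T) / np.maximum(R @ H.T, _EPS)
        R = W @ H + c[:, None]
        c *= Dm.sum(axis=1) / np.maximum(R.sum(axis=1), _EPS)
        err = np.linalg.norm(Dm - (W @ H + c[:, None])) / max(norm_D, _EPS)
        history.append(err)
        if prev is not None and abs(prev - err) < tol * max(prev, _EPS):
            break
        prev = err

    feat_idx = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(m)
    cell_idx = D.columns if isinstance(D, pd.DataFrame) else pd.RangeIndex(n)
    meta = [f"mf{i + 1}" for i in range(rank)]
    Wd = pd.DataFrame(W, index=feat_idx, columns=meta)
    Hd = pd.DataFrame(H, index=meta, columns=cell_idx)
    clusters = pd.Series(np.argmax(H, axis=0) + 1, index=cell_idx, name="cluster")
    return NMFDecomposition(
        W=Wd,
        H=Hd,
        offset=pd.Series(c, index=feat_idx, name="offset"),
        rank=rank,
        reconstruction_error=history[-1],
        error_history=history,
        cell_clusters=clusters,
    )


def rank_survey(
    D,
    ranks: Sequence[int] = tuple(range(1, 13)),
    seeds: Sequence[int] = (0, 1, 2),
    max_iter: int = 500,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Reconstruction error, sparsity and clustering stability per rank.

    Stability is the mean pairwise adjusted Rand index of argmax cell
    clusterings across random-initialization restarts (``seeds``); error and
    sparsity come from the deterministic NNDSVD fit.
    """
    if len(seeds) < 2:
        raise ValueError("stability needs at least two seeds")
    rows = []
    for r in ranks:
        ref = nmf(D, rank=r, max_iter=max_iter, tol=tol, init="nndsvd")
        WH = np.concatenate([ref.W.to_numpy().ravel(), ref.H.to_numpy().ravel()])
        sparsity = float(np.mean(WH < 1e-4 * max(WH.max(), _EPS)))
        labelings = [
            nmf(D, rank=r, seed=s, max_iter=max_iter, tol=tol, init="random").cell_clusters.to_numpy()
            for s in seeds
        ]
        aris = [
            adjusted_rand_score(a, b) for a, b in itertools.combinations(labelings, 2)
        ]
        stability = float(np.mean(aris)) if r > 1 else 1.0
        rows.append(
            {
                "rank": r,
                "error": ref.reconstruction_error,
                "sparsity": sparsity,
                "stability": stability,
            }
        )
    return pd.DataFrame(rows)


def assign_feature_sets(
    W: pd.DataFrame,
    H: Optional[pd.DataFrame] = None,
    min_sets: int = 2,
) -> pd.Series:
    """Group features into sets by hierarchical clustering of W's rows.

    When ``H`` is supplied, W's columns are first rescaled by the norms of the
    corresponding coefficient rows — the gauge in which column magnitude
    reflects how much each meta-feature actually contributes to the cells —
    so that weakly used meta-features do not dominate the normalized row
    patterns.  Rows are then normalized to unit sum, clustered with average
    linkage on the correlation distance, and the tree is cut at the number of
    clusters (from ``min_sets`` up to the rank) with the best silhouette.
    Labels are ordered by cluster size ("fs1" largest); all-zero, constant or
    near-zero-weight rows are labelled "unassigned".
    """
    Wm = W.to_numpy(dtype=float).copy()
    if H is not None:
        Wm = Wm * np.linalg.norm(np.asarray(H, dtype=float), axis=1)[None, :]
    rowsum = Wm.sum(axis=1)
    rowvar = Wm.var(axis=1)
    ok = (
        (rowsum > 0.1 * max(np.median(rowsum), _EPS))
        & (rowvar > _EPS * np.maximum(rowsum, 1.0) ** 2)
    )
    labels = np.array(["unassigned"] * Wm.shape[0], dtype=object)
    P = Wm[ok] / rowsum[ok][:, None]
    if P.shape[0] >= 3:
        corr = np.corrcoef(P)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        Zl = linkage(squareform(dist, checks=False), method="average")
        max_k = min(W.shape[1], P.shape[0] - 1)
        best_k, best_sil = None, -np.inf
        for k in range(min_sets, max(max_k, min_sets) + 1):
            cand = fcluster(Zl, k, criterion="maxclust")
            if np.unique(cand).size < 2:
                continue
            sil = silhouette_score(dist, cand, metric="precomputed")
            if sil > best_sil:
                best_k, best_sil = k, sil
        cand = fcluster(Zl, best_k, criterion="maxclust")
        order = pd.Series(cand).value_counts().index.to_list()  # by size desc
        remap = {old: f"fs{i + 1}" for i, old in enumerate(order)}
        labels[ok] = [remap[c] for c in cand]
    elif P.shape[0] > 0:
        labels[ok] = "fs1"
    return pd.Series(labels, index=W.index, name="feature_set")


# ---------------------------------------------------------------------------
# Rank-correlation distance and nonmetric MDS
# ---------------------------------------------------------------------------

def spearman_distance(Z) -> pd.DataFrame:
    """Cell-by-cell dissimilarity d = 1 - Spearman rho across all features."""
    values = Z.values if hasattr(Z, "values") and isinstance(Z.values, pd.DataFrame) else Z
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.asarray(values, dtype=float))
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two features per cell")
    ranks = stats.rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    if np.any(sd == 0):
        flat = list(values.index[sd == 0])
        raise ValueError(f"constant profile (rank correlation undefined) for cells: {flat}")
    rho = np.corrcoef(ranks)
    d = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=values.index, columns=values.index)


def nmds(
    d: pd.DataFrame,
    dims: int = 3,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, float]:
    """Nonmetric MDS embedding minimizing Kruskal stress-1.

    Runs ``n_restarts`` seeded initializations and returns the best embedding
    and its normalized stress (in [0, 1]).
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    coords, stress = smacof(
        dm,
        metric=False,
        n_components=dims,
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
        eps=1e-9,
        normalized_stress=True,
    )
    idx = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(dm.shape[0])
    cols = [f"MDS{i + 1}" for i in range(dims)]
    return pd.DataFrame(coords, index=idx, columns=cols), float(stress)


# ---------------------------------------------------------------------------
# Cluster-genotype enrichment
# ---------------------------------------------------------------------------

def cluster_enrichment(
    cell_clusters: Sequence, genotypes: Sequence, enriched_label: str = "KO"
) -> pd.DataFrame:
    """Upper-tail hypergeometric test for knockout overrepresentation.

    For each cluster of size N drawn from M cells of which n carry the
    knockout label, the p-value is P(X >= k) with k knockouts observed in the
    cluster.  Empty clusters get p = 1 and are flagged.
    """
    cl = pd.Series(list(cell_clusters))
    gt = pd.Series(list(genotypes))
    if len(cl) != len(gt):
        raise ValueError("cluster and genotype vectors must align")
    M = len(gt)
    n_ko = int((gt == enriched_label).sum())
    rows = []
    for label in sorted(cl.unique()):
        mask = cl == label
        N = int(mask.sum())
        k = int((gt[mask] == enriched_label).sum())
        if N == 0:
            p, flag = 1.0, "empty"
        else:
            p = float(stats.hypergeom.sf(k - 1, M, n_ko, N))
            flag = ""
        rows.append({"cluster": label, "size": N, f"n_{enriched_label}": k, "p": p, "flag": flag})
    return pd.DataFrame(rows)
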