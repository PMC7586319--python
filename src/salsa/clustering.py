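"""Latent-variable extraction and hierarchical cell clustering.

Cells are embedded by a truncated SVD of the gene-centered B(theta) score
matrix computed with a Lanczos bidiagonalization solver that honors
sparsity: absent entries act as zeros inside the linear operator and
centering is applied as an implicit rank-1 update, so the zero-filled
matrix is never materialized. Clusters come from Ward-linkage hierarchical
clustering on Euclidean distances in the latent space; prospective
clusters are later refined into cell majors by re-clustering on restricted
gene subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.linalg import LinearOperator, svds
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .scoring import ScoreSet

__all__ = [
    "Embedding",
    "ClusterAssignment",
    "truncated_svd",
    "ward_cluster",
    "choose_k",
    "refine_majors",
    "LatentWardClusterer",
]


@dataclass
class Embedding:
    coords: np.ndarray            # (n_cells, rank): right singular vectors * singular values
    rank: int
    singular_values: np.ndarray   # non-increasing
    explained: np.ndarray         # per-component fraction of centered Frobenius mass
    barcode_ids: list[str] | None = None

    def layout2d(self) -> np.ndarray:
        if self.rank >= 2:
            return self.coords[:, :2]
        return np.column_stack([self.coords[:, 0], np.zeros(len(self.coords))])


@dataclass
class ClusterAssignment:
    labels: dict[int, int]        # barcode index -> cluster id (1-based)
    stage: Literal["prospective", "major", "final"]
    k: int
    linkage_height: float
    layout2d: dict[int, tuple[float, float]]
    dropped: list[int] | None = None

    def label_array(self, n: int) -> np.ndarray:
        out = np.full(n, -1, dtype=int)
        for i, lab in self.labels.items():
            out[i] = lab
        return out


def truncated_svd(btheta: sp.spmatrix, rank: int, seed: int = 0,
                  center: bool = True) -> Embedding:
    """Top-``rank`` singular structure of the (implicitly) gene-centered score matrix.

    Rows are genes, columns are cells. Centering subtracts each gene's mean
    over its expressing cells from every column through a rank-1 update of
    the linear operator, preserving sparsity. Cell coordinates are the
    right singular vectors scaled by their singular values.
    """
    S = sp.csr_matrix(btheta, dtype=float)
    m, n = S.shape
    if rank > min(m, n):
        raise ValueError(f"rank {rank} exceeds min(n_genes, n_barcodes) = {min(m, n)}")

    nnz_row = np.diff(S.indptr)
    mu = np.zeros(m)
    expr = nnz_row > 0
    if center:
        row_sums = np.asarray(S.sum(axis=1)).ravel()
        mu[expr] = row_sums[expr] / nnz_row[expr]

    # centered Frobenius mass, exactly: ||S - mu 1^T||_F^2
    frob = float((S.multiply(S)).sum()) - 2.0 * float(mu @ np.asarray(S.sum(axis=1)).ravel()) \
        + n * float(mu @ mu)
    frob = max(frob, 0.0)
    if frob == 0.0:
        sv = np.zeros(rank)
        return Embedding(coords=np.zeros((n, rank)), rank=rank, singular_values=sv,
                         explained=np.zeros(rank))

    if rank >= min(m, n) - 1 or min(m, n) <= 32:
        dense = S.toarray() - mu[:, None]
        U, s, Vt = np.linalg.svd(dense, full_matrices=False)
        s, Vt = s[:rank], Vt[:rank]
    else:
        ones = np.ones(n)

        def mv(v):
            v = np.asarray(v).ravel()
            return S @ v - mu * float(ones @ v)

        def rmv(u):
            u = np.asarray(u).ravel()
            return S.T @ u - float(mu @ u) * ones

        op = LinearOperator((m, n), matvec=mv, rmatvec=rmv, dtype=float)
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(m, n))
        U, s, Vt = svds(op, k=rank, v0=v0)
        order = np.argsort(s)[::-1]
        s, Vt = s[order], Vt[order]

    coords = Vt.T * s
    return Embedding(coords=coords, rank=rank, singular_values=s,
                     explained=s ** 2 / frob)


def ward_cluster(embedding: Embedding, k: int | None = None,
                 height: float | None = None,
                 stage: str = "prospective") -> ClusterAssignment:
    """Ward-linkage agglomerative clustering in latent space."""
    if k is None and height is None:
        raise ValueError("supply either k or a cut height")
    n = len(embedding.coords)
    if k is not None and (k < 1 or k > n):
        raise ValueError(f"k={k} invalid for {n} cells")
    Z = linkage(embedding.coords, method="ward")
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
        cut_height = float(Z[-(k - 1), 2]) if k > 1 else float(Z[-1, 2] + 1)
    else:
        labels = fcluster(Z, t=height, criterion="distance")
        cut_height = float(height)
    layout = embedding.layout2d()
    return ClusterAssignment(
        labels={i: int(labels[i]) for i in range(n)},
        stage=stage, k=int(len(np.unique(labels))), linkage_height=cut_height,
        layout2d={i: (float(layout[i, 0]), float(layout[i, 1])) for i in range(n)},
    )


def choose_k(embedding: Embedding, k_range: Sequence[int]) -> int:
    """k maximizing mean silhouette over the candidate range; ties go to the smallest k."""
    ks = [k for k in k_range if 2 <= k < len(embedding.coords)]
    if not ks:
        raise ValueError("empty or infeasible k range")
    Z = linkage(embedding.coords, method="ward")
    best_k, best_s = None, -np.inf
    for k in sorted(ks):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(embedding.coords, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        best_k = min(ks)
    return int(best_k)


def refine_majors(score_set: ScoreSet, marker_genes, k: int | None = None,
                  k_range: Sequence[int] = range(2, 13), rank: int | None = None,
                  seed: int = 0, stage: str = "major") -> ClusterAssignment:
    """Re-embed and re-cluster cells using only the given marker genes' scores.

    Cells with no marker-gene entry cannot be placed and are dropped (and
    reported on the returned assignment).
    """
    genes = sorted(set(int(g) for g in marker_genes))
    if not genes:
        raise ValueError("marker gene set is empty")
    sub = score_set.btheta.tocsr()[genes, :]
    keep = np.nonzero(np.diff(sub.tocsc().indptr) > 0)[0]
    if keep.size == 0:
        raise ValueError("no cell expresses any marker gene")
    dropped = [int(c) for c in range(sub.shape[1]) if c not in set(keep.tolist())]
    sub = sub[:, keep]
    r = rank if rank is not None else min(50, min(sub.shape) - 1)
    r = max(r, 1)
    emb = truncated_svd(sub, rank=r, seed=seed)
    kk = k if k is not None else choose_k(emb, k_range)
    assign = ward_cluster(emb, k=kk, stage=stage)
    # re-map positions back to original barcode indices
    labels = {int(keep[i]): lab for i, lab in assign.labels.items()}
    layout = {int(keep[i]): xy for i, xy in assign.layout2d.items()}
    return ClusterAssignment(labels=labels, stage=stage, k=assign.k,
                             linkage_height=assign.linkage_height,
                             layout2d=layout, dropped=dropped)


class LatentWardClusterer(BaseEstimator, ClusterMixin):
    """SVD embedding + Ward clustering of cells from a B(theta) score stack.

    ``fit`` accepts a genes x cells sparse score matrix (or a ScoreSet) and
    exposes ``embedding_``, ``assignment_`` and sklearn-style ``labels_``.

    Parameters
    ----------
    rank : int or None
        Latent dimensionality; default min(50, min(shape) - 1).
    k : int or None
        Number of clusters; None selects k by mean silhouette over k_range.
    """

    def __init__(self, rank: int | None = None, k: int | None = None,
                 k_range: Sequence[int] = tuple(range(2, 13)),
                 center: bool = True, seed: int = 0):
        self.rank = rank
        self.k = k
        self.k_range = k_range
        self.center = center
        self.seed = seed

    def fit(self, X, y=None) -> "LatentWardClusterer":
        btheta = X.btheta if isinstance(X, ScoreSet) else X
        btheta = sp.csr_matrix(btheta)
        r = self.rank if self.rank is not None else min(50, min(btheta.shape) - 1)
        r = max(r, 1)
        self.embedding_ = truncated_svd(btheta, rank=r, seed=self.seed, center=self.center)
        kk = self.k if self.k is not None else choose_k(self.embedding_, self.k_range)
        self.assignment_ = ward_cluster(self.embedding_, k=kk)
        self.labels_ = self.assignment_.label_array(btheta.shape[1])
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
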