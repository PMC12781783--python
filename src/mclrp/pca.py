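"""PCA reduction of the expression matrix.

The solver constrains the completed response matrix toward the span of the
principal-component score matrix U of the (column-centered) expression
profiles; the loadings map per-component drug coefficients back to genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .data import ExpressionMatrix


@dataclass
class ExpressionPCA:
    """Principal-component decomposition of a centered expression matrix.

    ``scores`` (m x k) are the sample coordinates U used by the solver —
    score columns, not re-orthonormalized left singular vectors, so U^T U is
    diagonal but not the identity. ``loadings`` (n x k) are the gene-space
    directions W, with ``scores = (X - col_means) @ loadings``.
    """

    scores: np.ndarray
    loadings: np.ndarray
    col_means: np.ndarray
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    gene_ids: Optional[list[str]] = None

    def save(self, path: str | Path) -> None:
        np.savez(path, scores=self.scores, loadings=self.loadings,
                 col_means=self.col_means,
                 singular_values=self.singular_values,
                 explained_variance_ratio=self.explained_variance_ratio,
                 k=self.k,
                 gene_ids=np.asarray(self.gene_ids if self.gene_ids else []))

    @classmethod
    def load(cls, path: str | Path) -> "ExpressionPCA":
        with np.load(path, allow_pickle=False) as z:
            genes = [str(g) for g in z["gene_ids"]] or None
            return cls(z["scores"], z["loadings"], z["col_means"],
                       z["singular_values"],
                       z["explained_variance_ratio"], int(z["k"]), genes)


def fit_pca(X: ExpressionMatrix | np.ndarray,
            n_components: Optional[int] = None,
            variance_target: Optional[float] = None,
            scale_genes: bool = False) -> ExpressionPCA:
    """Fit PCA on the expression matrix via SVD of the centered data.

    Exactly one of ``n_components`` / ``variance_target`` selects k: a fixed
    component count, or the smallest k whose cumulative explained-variance
    ratio reaches the target (default 0.95), capped at the matrix rank and
    at m-1. Genes are centered but not variance-scaled unless
    ``scale_genes`` is set. Component signs follow the convention that each
    loading column's largest-magnitude entry is positive.
    """
    if n_components is not None and variance_target is not None:
        raise ValueError("give n_components or variance_target, not both")
    if n_components is None and variance_target is None:
        variance_target = 0.95
    gene_ids = None
    if isinstance(X, ExpressionMatrix):
        gene_ids = list(X.gene_ids)
        X = X.values
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if m < 2:
        raise ValueError("need at least 2 cell lines for PCA")

    col_means = X.mean(axis=0)
    Xc = X - col_means
    if scale_genes:
        sds = Xc.std(axis=0, ddof=1)
        sds[sds == 0] = 1.0
        Xc = Xc / sds

    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > 1e-12 * s[0]).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("expression matrix is constant (rank 0)")
    max_k = min(rank, m - 1)

    total_var = (s**2).sum()
    evr_full = s**2 / total_var
    if variance_target is not None:
        if not 0 < variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")
        cum = np.cumsum(evr_full[:max_k])
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, max_k)
    else:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if n_components > max_k:
            raise ValueError(
                f"requested {n_components} components but attainable rank "
                f"(capped at m-1) is {max_k}")
        k = int(n_components)

    loadings = Vt[:k].T.copy()
    # deterministic signs across linear-algebra backends
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xc @ loadings
    return ExpressionPCA(scores, loadings, col_means, s[:k].copy(),
                         evr_full[:k].copy(), k, gene_ids)


def back_project(pca: ExpressionPCA, coeffs: np.ndarray) -> np.ndarray:
    """Map component-space drug coefficients (k x p) to gene weights (n x p)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 1:
        coeffs = coeffs[:, None]
    if coeffs.shape[0] != pca.k:
        raise ValueError(
            f"coeffs has {coeffs.shape[0]} rows but PCA retains {pca.k} "
            "components")
    return pca.loadings @ coeffs
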