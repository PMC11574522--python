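"""Gene-gene Pearson co-expression matrices, hierarchical ordering and block scores.

The analysis mirrors a two-condition co-expression comparison: Pearson
correlations between all gene pairs are computed across single cells of each
condition on log-normalized values; hierarchical clustering is performed on
the treated-condition matrix and the resulting dendrogram leaf order is
transferred to the control matrix, so gained or lost co-expression blocks
line up visually.  ``block_score`` quantifies a gene set's co-expression
coherence as the mean within-set off-diagonal correlation next to the mean
set-to-background correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy import sparse

__all__ = [
    "CorrelationMatrix",
    "ClusterOrdering",
    "BlockScore",
    "pearson_matrix",
    "hierarchical_order",
    "apply_ordering",
    "block_score",
    "longest_contiguous_run",
]


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson matrix; undefined (zero-variance) entries are NaN."""

    genes: list[str]
    values: np.ndarray
    condition: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} genes")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], np.asarray(self.values.T)[finite], atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        vals = self.values[finite]
        if vals.size and (vals.min() < -1.0 - 1e-9 or vals.max() > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def missing_genes(self) -> list[str]:
        bad = ~np.isfinite(np.diag(self.values))
        return [g for g, m in zip(self.genes, bad) if m]

    def drop_missing(self) -> "CorrelationMatrix":
        keep = np.isfinite(np.diag(self.values))
        idx = np.where(keep)[0]
        return CorrelationMatrix(
            genes=[self.genes[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            condition=self.condition,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)


@dataclass
class ClusterOrdering:
    """A dendrogram leaf order (permutation of gene ids) and its provenance."""

    genes: list[str]
    source_condition: str | None = None
    linkage_description: str = "complete linkage, euclidean distance on correlation rows"

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ordering contains duplicate genes")


@dataclass
class BlockScore:
    within: float
    between: float
    n_missing_excluded: int = 0


def pearson_matrix(adata, genes=None, cells=None, condition: str | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlation of (log-normalized) gene values across cells.

    ``adata`` is an AnnData whose ``.X`` holds the values to correlate;
    ``genes`` preselects a panel and ``cells`` a boolean mask or index list
    (e.g. one cluster of one condition).  Zero-variance genes yield NaN rows
    (recorded as missing, never silently 0).  Fewer than 3 cells is an error.
    """
    sub = adata
    if cells is not None:
        sub = sub[cells]
    if genes is not None:
        missing = [g for g in genes if g not in sub.var_names]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing}")
        sub = sub[:, list(genes)]
    if sub.n_obs < 3:
        raise ValueError(f"need at least 3 cells to correlate, got {sub.n_obs}")
    X = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X)
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    zero_var = sd == 0
    R[zero_var, :] = np.nan
    R[:, zero_var] = np.nan
    np.fill_diagonal(R, np.where(zero_var, np.nan, 1.0))
    return CorrelationMatrix(genes=list(sub.var_names), values=R, condition=condition)


def hierarchical_order(
    corr: CorrelationMatrix, method: str = "complete", metric: str = "euclidean"
) -> ClusterOrdering:
    """Agglomerative clustering of correlation-matrix rows; returns the leaf order.

    Distances are computed between rows of the correlation matrix (default
    Euclidean) with complete linkage.  Missing entries must be dropped first
    (``drop_missing``); they raise an error listing the offending genes.
    Ties in merge heights are resolved by scipy's deterministic ordering
    (lower original index first).
    """
    if corr.missing_genes or not np.all(np.isfinite(corr.values)):
        raise ValueError(
            "correlation matrix has missing entries; drop zero-variance genes first: "
            f"{corr.missing_genes}"
        )
    if len(corr.genes) == 1:
        return ClusterOrdering(genes=list(corr.genes), source_condition=corr.condition)
    Z = linkage(corr.values, method=method, metric=metric)
    order = leaves_list(Z)
    return ClusterOrdering(
        genes=[corr.genes[i] for i in order],
        source_condition=corr.condition,
        linkage_description=f"{method} linkage, {metric} distance on correlation rows",
    )


def apply_ordering(corr: CorrelationMatrix, ordering: ClusterOrdering) -> CorrelationMatrix:
    """Symmetric row/column permutation of the matrix into the given gene order."""
    if set(ordering.genes) != set(corr.genes):
        extra = sorted(set(ordering.genes) - set(corr.genes))
        missing = sorted(set(corr.genes) - set(ordering.genes))
        raise ValueError(
            f"ordering does not cover the matrix's genes (extra: {extra[:5]}, missing: {missing[:5]})"
        )
    pos = {g: i for i, g in enumerate(corr.genes)}
    idx = np.array([pos[g] for g in ordering.genes])
    return CorrelationMatrix(
        genes=list(ordering.genes),
        values=corr.values[np.ix_(idx, idx)],
        condition=corr.condition,
    )


def block_score(corr: CorrelationMatrix, gene_set) -> BlockScore:
    """Mean within-set off-diagonal R and mean set-to-background R.

    Missing (NaN) entries are excluded, with their count reported.
    """
    gene_set = list(gene_set)
    if len(gene_set) < 2:
        raise ValueError("gene_set must contain at least 2 genes")
    missing = [g for g in gene_set if g not in corr.genes]
    if missing:
        raise KeyError(f"gene_set members absent from matrix: {missing}")
    pos = {g: i for i, g in enumerate(corr.genes)}
    inside = np.array([pos[g] for g in gene_set])
    outside = np.array([i for i in range(len(corr.genes)) if i not in set(inside)])
    within_block = corr.values[np.ix_(inside, inside)]
    mask = ~np.eye(len(inside), dtype=bool)
    within_vals = within_block[mask]
    between_vals = (
        corr.values[np.ix_(inside, outside)].ravel() if outside.size else np.array([])
    )
    n_missing = int(np.isnan(within_vals).sum() + np.isnan(between_vals).sum())
    w_ok = within_vals[~np.isnan(within_vals)]
    b_ok = between_vals[~np.isnan(between_vals)]
    within = float(w_ok.mean()) if w_ok.size else float("nan")
    between = float(b_ok.mean()) if b_ok.size else 0.0
    return BlockScore(within=within, between=between, n_missing_excluded=n_missing)


def longest_contiguous_run(ordering: ClusterOrdering, gene_set) -> int:
    """Length of the longest run of consecutive leaves that all belong to ``gene_set``."""
    members = set(gene_set)
    best = run = 0
    for g in ordering.genes:
        run = run + 1 if g in members else 0
        best = max(best, run)
    return best
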