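"""Cell- and gene-level filtering and log-normalization for single-cell count matrices.

Matrices are held as :class:`anndata.AnnData` (cells x genes), with per-cell
metadata in ``.obs`` (``condition``, ``cluster``, ``n_features``, ``n_counts``,
``percent_mito``) and per-gene metadata in ``.var`` (``half_life`` in minutes,
``is_mito``).  Quality filters use strict inequalities: cells are kept when
``n_features < 12000``, ``n_counts < 150000`` and ``percent_mito < 8``; genes
are kept when expressed (nonzero) in at least 10 cells.  The pipeline order is
fixed: cells are filtered first, then genes — a gene's supporting cell count
is evaluated on the retained cells only.

Normalization is the standard single-cell log-normalization: per-cell scaling
to ``scale_factor`` total counts followed by log1p, i.e.
``ln(1 + scale_factor * count / cell_total)``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from scipy.io import mmread

__all__ = [
    "MAX_FEATURES",
    "MAX_COUNTS",
    "MAX_MITO_PCT",
    "MIN_CELLS_PER_GENE",
    "compute_qc_metrics",
    "filter_cells",
    "filter_genes",
    "log_normalize",
    "preprocess_pipeline",
    "read_study",
    "counts_by_gene",
]

logger = logging.getLogger(__name__)

MAX_FEATURES = 12_000
MAX_COUNTS = 150_000
MAX_MITO_PCT = 8.0
MIN_CELLS_PER_GENE = 10


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def compute_qc_metrics(adata: ad.AnnData) -> ad.AnnData:
    """(Re)compute per-cell QC covariates from the matrix, in place.

    ``n_features`` is the number of genes detected per cell, ``n_counts`` the
    total counts (UMI analog) and ``percent_mito`` the percentage of counts on
    genes flagged ``is_mito`` in ``.var`` (0 if the flag is absent).
    """
    X = adata.X
    if sparse.issparse(X):
        adata.obs["n_features"] = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        adata.obs["n_features"] = (np.asarray(X) > 0).sum(axis=1)
        totals = np.asarray(X).sum(axis=1)
    adata.obs["n_counts"] = totals
    if "is_mito" in adata.var:
        mito = adata[:, adata.var["is_mito"].astype(bool)].X
        mito_totals = np.asarray(mito.sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * mito_totals / totals, 0.0)
        adata.obs["percent_mito"] = pct
    elif "percent_mito" not in adata.obs:
        adata.obs["percent_mito"] = 0.0
    return adata


def filter_cells(
    adata: ad.AnnData,
    max_features: float = MAX_FEATURES,
    max_counts: float = MAX_COUNTS,
    max_mito_pct: float = MAX_MITO_PCT,
    recompute: bool = True,
) -> ad.AnnData:
    """Keep cells satisfying all three strict inequalities; returns a copy.

    A cell at exactly a threshold (e.g. ``n_features == 12000``) is removed.
    """
    if adata.n_obs == 0:
        return adata.copy()
    if recompute or "n_features" not in adata.obs:
        adata = compute_qc_metrics(adata.copy())
    keep = (
        (adata.obs["n_features"] < max_features)
        & (adata.obs["n_counts"] < max_counts)
        & (adata.obs["percent_mito"] < max_mito_pct)
    ).to_numpy()
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_cells removed %d of %d cells", removed, adata.n_obs)
    return adata[keep].copy()


def filter_genes(adata: ad.AnnData, min_cells: int = MIN_CELLS_PER_GENE) -> ad.AnnData:
    """Keep genes with nonzero counts in at least ``min_cells`` cells; returns a copy."""
    out = adata.copy()
    if out.n_obs == 0 or out.n_vars == 0:
        return out
    sc.pp.filter_genes(out, min_cells=min_cells)
    removed = adata.n_vars - out.n_vars
    if removed:
        logger.info("filter_genes removed %d of %d genes", removed, adata.n_vars)
    return out


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Per-cell scaling to ``scale_factor`` counts then log1p; raw counts kept in a layer.

    Cells with zero total counts are rejected with an error naming the cell.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[totals == 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad[:10]}")
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    out.X = out.X.astype(np.float64)
    sc.pp.normalize_total(out, target_sum=scale_factor)
    sc.pp.log1p(out)
    return out


def preprocess_pipeline(
    adata: ad.AnnData,
    max_features: float = MAX_FEATURES,
    max_counts: float = MAX_COUNTS,
    max_mito_pct: float = MAX_MITO_PCT,
    min_cells: int = MIN_CELLS_PER_GENE,
) -> ad.AnnData:
    """The fixed filtering order: cells first, then genes."""
    out = filter_cells(adata, max_features, max_counts, max_mito_pct)
    return filter_genes(out, min_cells)


# --------------------------------------------------------------------------- I/O


def _read_condition(cond_dir: Path) -> ad.AnnData:
    matrix = mmread(cond_dir / "matrix.mtx").tocsr().astype(np.int64)
    features = pd.read_csv(cond_dir / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(cond_dir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if matrix.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"{cond_dir}: matrix shape {matrix.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    adata = ad.AnnData(X=matrix.T.tocsr())
    adata.obs_names = barcodes.tolist()
    adata.var_names = features.tolist()
    return adata


def read_study(study_dir) -> dict[str, ad.AnnData]:
    """Read a written study directory back into one AnnData per condition.

    Matrices are Matrix Market (genes x cells) with ``features.tsv`` /
    ``barcodes.tsv`` companions; per-cell metadata and per-gene half-lives are
    merged from ``cell_metadata.tsv`` and ``half_lives.tsv`` when present.
    """
    study_dir = Path(study_dir)
    meta = None
    meta_path = study_dir / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="barcode")
    half_lives = None
    hl_path = study_dir / "half_lives.tsv"
    if hl_path.exists():
        half_lives = pd.read_csv(hl_path, sep="\t", index_col="gene_id")["half_life_min"]
    conditions = {}
    for cond_dir in sorted(p for p in study_dir.iterdir() if (p / "matrix.mtx").exists()):
        adata = _read_condition(cond_dir)
        if meta is not None:
            cond_meta = meta.loc[adata.obs_names]
            for col in cond_meta.columns:
                adata.obs[col] = cond_meta[col].values
        if half_lives is not None:
            adata.var["half_life"] = half_lives.reindex(adata.var_names).values
        if "is_mito" not in adata.var:
            adata.var["is_mito"] = [g.startswith("MT-") for g in adata.var_names]
        compute_qc_metrics(adata)
        conditions[cond_dir.name] = adata
    if not conditions:
        raise FileNotFoundError(f"no condition directories with matrix.mtx under {study_dir}")
    return conditions


def counts_by_gene(
    adata: ad.AnnData, cluster: str | None = "1", exclude_mito: bool = True
) -> dict[str, np.ndarray]:
    """Raw per-cell count vectors keyed by gene, restricted to one cluster."""
    sub = adata
    if cluster is not None and "cluster" in adata.obs:
        sub = adata[adata.obs["cluster"].astype(str) == str(cluster)]
    if exclude_mito and "is_mito" in sub.var:
        sub = sub[:, ~sub.var["is_mito"].astype(bool)]
    X = _dense(sub.X).astype(np.int64)
    return {gene: X[:, j].copy() for j, gene in enumerate(sub.var_names)}
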