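"""High-level workflow steps binding the analysis stages together.

These functions are the programmatic counterparts of the CLI subcommands:
preprocess a study, fit every gene per condition, compare conditions, and run
the co-expression analysis.  They operate on the in-memory ``Study`` /
AnnData objects and plain DataFrames so that scripts and tests can compose
them without touching the command line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import FOLD_CHANGE_QUANTITIES, log2_fold_changes, wilcoxon_geneset
from .coexpression import (
    apply_ordering,
    block_score,
    hierarchical_order,
    pearson_matrix,
)
from .inference import fit_gene_table
from .preprocess import counts_by_gene, log_normalize, preprocess_pipeline

__all__ = ["fit_study", "compare_fits", "coexpress_study", "DEFAULT_FIT_SETTINGS"]

logger = logging.getLogger(__name__)

#: study-scale MCMC settings (per-gene chains are shorter than the single-gene
#: default because ~600 fits run in one pass; see the methods note)
DEFAULT_FIT_SETTINGS = {"n_steps": 1200, "n_burn": 400}


def fit_study(
    conditions: dict,
    half_lives,
    cluster: str | None = "1",
    n_alleles: int = 2,
    seed: int = 0,
    genes=None,
    n_steps: int = DEFAULT_FIT_SETTINGS["n_steps"],
    n_burn: int = DEFAULT_FIT_SETTINGS["n_burn"],
    preprocess: bool = True,
) -> pd.DataFrame:
    """Filter, then fit every gene of every condition; returns one flat table.

    ``conditions`` maps condition name -> AnnData of raw counts.  Cells are
    QC-filtered and genes must be expressed in >= 10 cells before fitting;
    mitochondrial-flagged genes are excluded from kinetics.  The per-gene MCMC
    seed is derived from ``seed`` and the condition name so the two conditions
    use independent, reproducible streams.
    """
    if not conditions:
        raise ValueError("no conditions to fit")
    tables = []
    for i, (cond, adata) in enumerate(sorted(conditions.items())):
        if adata.n_obs == 0 or adata.n_vars == 0:
            raise ValueError(f"condition {cond!r} has an empty matrix")
        pp = preprocess_pipeline(adata) if preprocess else adata
        cbg = counts_by_gene(pp, cluster=cluster)
        if genes is not None:
            cbg = {g: cbg[g] for g in genes if g in cbg}
        logger.info("fitting %d genes for condition %s", len(cbg), cond)
        table = fit_gene_table(
            cbg,
            half_lives,
            condition=cond,
            n_alleles=n_alleles,
            n_steps=n_steps,
            n_burn=n_burn,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0]),
        )
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def compare_fits(
    fits: pd.DataFrame,
    signature,
    treated: str = "treated",
    control: str = "control",
) -> tuple[pd.DataFrame, dict]:
    """Fold changes and signature-vs-background tests from a combined fit table."""
    signature = list(signature)
    if not signature:
        raise ValueError("signature gene set is empty; nothing to compare")
    by_cond = {c: df for c, df in fits.groupby("condition")}
    for c in (treated, control):
        if c not in by_cond:
            raise KeyError(f"condition {c!r} absent from fit table ({sorted(by_cond)})")
    mismatch = set(by_cond[treated]["gene_id"]) ^ set(by_cond[control]["gene_id"])
    if mismatch:
        logger.warning("gene sets differ between conditions: %s", sorted(mismatch)[:10])
    fc = log2_fold_changes(by_cond[treated], by_cond[control])
    comparisons = {
        q: wilcoxon_geneset(fc, signature, q) for q in FOLD_CHANGE_QUANTITIES
    }
    return fc, comparisons


def coexpress_study(
    conditions: dict,
    genes=None,
    order_from: str = "treated",
    cluster: str | None = "1",
) -> dict:
    """Per-condition correlation matrices with the ordering taken from one condition.

    Each condition's raw matrix is filtered and log-normalized, correlations
    are computed over the (non-mitochondrial) gene panel, zero-variance genes
    are dropped, hierarchical clustering is run on ``order_from`` and its leaf
    order applied to every condition.  Returns correlation matrices (raw and
    reordered), the ordering, and per-condition signature block scores when a
    panel is given.
    """
    if order_from not in conditions:
        raise KeyError(f"order_from condition {order_from!r} not in {sorted(conditions)}")
    corrs = {}
    for cond, adata in conditions.items():
        pp = preprocess_pipeline(adata)
        if cluster is not None and "cluster" in pp.obs:
            pp = pp[pp.obs["cluster"].astype(str) == str(cluster)].copy()
        norm = log_normalize(pp)
        panel = genes
        if panel is None:
            mito = norm.var["is_mito"].astype(bool) if "is_mito" in norm.var else None
            panel = [g for i, g in enumerate(norm.var_names) if mito is None or not mito.iloc[i]]
        panel = [g for g in panel if g in norm.var_names]
        corrs[cond] = pearson_matrix(norm, genes=panel, condition=cond).drop_missing()
    # restrict to genes defined in every condition so the ordering transfers
    common = set(corrs[order_from].genes)
    for c in corrs.values():
        common &= set(c.genes)
    for cond in list(corrs):
        keep = [g for g in corrs[cond].genes if g in common]
        idx = [corrs[cond].genes.index(g) for g in keep]
        corrs[cond] = type(corrs[cond])(
            genes=keep,
            values=corrs[cond].values[np.ix_(idx, idx)],
            condition=cond,
        )
    ordering = hierarchical_order(corrs[order_from])
    ordered = {cond: apply_ordering(c, ordering) for cond, c in corrs.items()}
    return {"correlations": corrs, "ordering": ordering, "ordered": ordered}


def block_scores(result: dict, gene_set) -> dict:
    """Within/between block scores of a gene set for every condition of a
    :func:`coexpress_study` result."""
    out = {}
    for cond, corr in result["correlations"].items():
        present = [g for g in gene_set if g in corr.genes]
        score = block_score(corr, present)
        out[cond] = {"within": score.within, "between": score.between,
                     "n_genes": len(present)}
    return out
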