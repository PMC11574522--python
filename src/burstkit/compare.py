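"""Two-condition comparison of fitted bursting kinetics.

Per-gene log2 fold changes (treated over control) of expression, burst
frequency and burst size are computed from fit tables, restricted to genes
passing quality control in both conditions.  Expression uses the observed
mean raw counts (assumption-free); frequency and burst size use posterior
medians.  A signature gene set is compared against all other QC-passing
genes with a two-sided Wilcoxon (Mann-Whitney) rank-sum test, exact when the
combined sample is small and tie-free, with the tie-corrected normal
approximation otherwise.  Ploidy sensitivity refits the treated condition
under 4, 8 and 16 assumed allele copies (control fixed at 2) and repeats the
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "FOLD_CHANGE_QUANTITIES",
    "GeneSetComparison",
    "log2_fold_changes",
    "wilcoxon_geneset",
    "ploidy_sensitivity",
]

logger = logging.getLogger(__name__)

#: quantity name -> fit-table column holding its per-gene value
FOLD_CHANGE_QUANTITIES = {
    "expression": "mean_expression",
    "frequency": "frequency_median",
    "burst_size": "burst_size_median",
}

#: largest tie-free combined sample for which the exact null is enumerated
_EXACT_N_MAX = 25


@dataclass
class GeneSetComparison:
    """Signature-vs-background rank-sum comparison of one fold-change quantity."""

    quantity: str
    signature_genes: list[str]
    n_signature: int
    n_background: int
    statistic: float
    pvalue: float
    method: str
    median_signature: float
    median_background: float

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "n_signature": self.n_signature,
            "n_background": self.n_background,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "method": self.method,
            "median_signature": self.median_signature,
            "median_background": self.median_background,
        }


def log2_fold_changes(fits_treated: pd.DataFrame, fits_control: pd.DataFrame) -> pd.DataFrame:
    """Per-gene log2(treated/control) of expression, frequency and burst size.

    Both inputs are fit tables keyed by ``gene_id`` (as produced by
    ``fit_gene_table``).  Only genes passing QC in both conditions are
    emitted; genes with a nonpositive value in either condition are skipped
    with a logged reason.
    """
    merged = fits_treated.merge(
        fits_control, on="gene_id", suffixes=("_treated", "_control"), how="inner"
    )
    merged = merged[
        merged["qc_pass_treated"].astype(bool) & merged["qc_pass_control"].astype(bool)
    ]
    records = []
    for _, row in merged.iterrows():
        rec = {"gene_id": row["gene_id"], "qc_pass_both": True}
        ok = True
        for quantity, col in FOLD_CHANGE_QUANTITIES.items():
            num = row[f"{col}_treated"]
            den = row[f"{col}_control"]
            if not (np.isfinite(num) and np.isfinite(den) and num > 0 and den > 0):
                logger.info(
                    "gene %s skipped: nonpositive %s (treated=%r, control=%r)",
                    row["gene_id"], quantity, num, den,
                )
                ok = False
                break
            rec[f"log2fc_{quantity}"] = float(np.log2(num / den))
        if ok:
            records.append(rec)
    cols = ["gene_id"] + [f"log2fc_{q}" for q in FOLD_CHANGE_QUANTITIES] + ["qc_pass_both"]
    return pd.DataFrame(records, columns=cols)


def wilcoxon_geneset(
    records: pd.DataFrame, signature, quantity: str = "burst_size"
) -> GeneSetComparison:
    """Two-sided rank-sum test of a fold-change quantity, signature vs background.

    Exact null for combined n <= 25 without ties; normal approximation with
    tie correction otherwise.  Both groups must contain at least 2 genes.
    """
    if quantity not in FOLD_CHANGE_QUANTITIES:
        raise KeyError(f"unknown quantity {quantity!r}; one of {list(FOLD_CHANGE_QUANTITIES)}")
    col = f"log2fc_{quantity}"
    signature = [str(g) for g in signature]
    in_sig = records["gene_id"].isin(signature)
    x = records.loc[in_sig, col].to_numpy(dtype=float)
    y = records.loc[~in_sig, col].to_numpy(dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"need >= 2 genes per group, got {x.size} signature and {y.size} background"
        )
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= _EXACT_N_MAX and tie_free) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GeneSetComparison(
        quantity=quantity,
        signature_genes=sorted(records.loc[in_sig, "gene_id"]),
        n_signature=int(x.size),
        n_background=int(y.size),
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method=method,
        median_signature=float(np.median(x)),
        median_background=float(np.median(y)),
    )


def ploidy_sensitivity(
    counts_treated,
    counts_control,
    half_lives,
    signature,
    allele_grid=(2, 4, 8, 16),
    control_n_alleles: int = 2,
    seed: int = 0,
    quantities=("burst_size", "frequency", "expression"),
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Refit the treated condition at each assumed allele count and re-test.

    ``counts_treated`` / ``counts_control`` map gene id -> per-cell raw counts;
    the control is fitted once at ``control_n_alleles``.  Returns a summary
    table (one row per ploidy x quantity) and a dict with each ploidy's full
    fold-change table and comparisons.  The entry for the control's allele
    count reproduces the standard pipeline output exactly for the same seed.
    """
    from .inference import fit_gene_table

    fits_control = fit_gene_table(
        counts_control, half_lives, condition="control",
        n_alleles=control_n_alleles, seed=seed, **fit_kwargs,
    )
    rows = []
    details = {}
    for ploidy in allele_grid:
        fits_treated = fit_gene_table(
            counts_treated, half_lives, condition="treated",
            n_alleles=int(ploidy), seed=seed, **fit_kwargs,
        )
        fc = log2_fold_changes(fits_treated, fits_control)
        comparisons = {}
        for quantity in quantities:
            comp = wilcoxon_geneset(fc, signature, quantity)
            comparisons[quantity] = comp
            rows.append(
                {
                    "n_alleles_treated": int(ploidy),
                    "quantity": quantity,
                    "pvalue": comp.pvalue,
                    "median_signature": comp.median_signature,
                    "median_background": comp.median_background,
                    "n_signature": comp.n_signature,
                    "n_background": comp.n_background,
                }
            )
        details[int(ploidy)] = {
            "fits_treated": fits_treated,
            "fold_changes": fc,
            "comparisons": comparisons,
        }
    return pd.DataFrame(rows), details
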