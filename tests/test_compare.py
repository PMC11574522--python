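"""Fold-change computation and the signature-vs-background rank-sum test."""

import numpy as np
import pandas as pd
import pytest

from burstkit.compare import (
    log2_fold_changes,
    ploidy_sensitivity,
    wilcoxon_geneset,
)
from burstkit.simulate import SimulationConfig, betapoisson_counts
from burstkit.core import TelegraphRates
from burstkit.inference import fit_gene_table


def fit_table(genes, expression=10.0, frequency=0.1, burst=5.0, qc=True):
    rows = []
    for i, g in enumerate(genes):
        e = expression[i] if np.ndim(expression) else expression
        f = frequency[i] if np.ndim(frequency) else frequency
        b = burst[i] if np.ndim(burst) else burst
        q = qc[i] if np.ndim(qc) else qc
        rows.append(
            {"gene_id": g, "mean_expression": e, "frequency_median": f,
             "burst_size_median": b, "qc_pass": q}
        )
    return pd.DataFrame(rows)


class TestLog2FoldChanges:
    def test_identical_medians_give_zero(self):
        t = fit_table(["a", "b"])
        fc = log2_fold_changes(t, t.copy())
        assert np.allclose(fc[["log2fc_expression", "log2fc_frequency", "log2fc_burst_size"]], 0.0)

    def test_burst_doubling_gives_one(self):
        treated = fit_table(["a"], burst=4.0)
        control = fit_table(["a"], burst=2.0)
        fc = log2_fold_changes(treated, control)
        assert fc.loc[0, "log2fc_burst_size"] == pytest.approx(1.0)

    def test_qc_failures_excluded(self):
        treated = fit_table(["a", "b"], qc=[True, False])
        control = fit_table(["a", "b"], qc=[True, True])
        fc = log2_fold_changes(treated, control)
        assert list(fc.gene_id) == ["a"]
        assert fc.qc_pass_both.all()

    def test_nonpositive_control_skipped(self, caplog):
        treated = fit_table(["a", "b"])
        control = fit_table(["a", "b"], burst=[0.0, 2.0])
        with caplog.at_level("INFO"):
            fc = log2_fold_changes(treated, control)
        assert list(fc.gene_id) == ["b"]

    def test_label_swap_negates_fold_changes(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(8)]
        t = fit_table(genes, expression=rng.uniform(1, 20, 8),
                      frequency=rng.uniform(0.01, 1, 8), burst=rng.uniform(1, 30, 8))
        c = fit_table(genes, expression=rng.uniform(1, 20, 8),
                      frequency=rng.uniform(0.01, 1, 8), burst=rng.uniform(1, 30, 8))
        ab = log2_fold_changes(t, c).set_index("gene_id")
        ba = log2_fold_changes(c, t).set_index("gene_id")
        for col in ("log2fc_expression", "log2fc_frequency", "log2fc_burst_size"):
            assert np.allclose(ab[col], -ba[col])


def records(sig_vals, bg_vals, quantity="burst_size"):
    genes = [f"s{i}" for i in range(len(sig_vals))] + [f"b{i}" for i in range(len(bg_vals))]
    df = pd.DataFrame({"gene_id": genes})
    for q in ("expression", "frequency", "burst_size"):
        df[f"log2fc_{q}"] = 0.0
    df[f"log2fc_{quantity}"] = list(sig_vals) + list(bg_vals)
    return df, [f"s{i}" for i in range(len(sig_vals))]


class TestWilcoxon:
    def test_exact_small_sample_pvalue(self):
        df, sig = records([1.0, 2.0], [3.0, 4.0])
        comp = wilcoxon_geneset(df, sig, "burst_size")
        assert comp.method == "exact"
        assert comp.pvalue == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        df, sig = records([1.0, 2.0], [1.0, 2.0])
        comp = wilcoxon_geneset(df, sig, "burst_size")
        assert comp.pvalue == pytest.approx(1.0)

    def test_empty_group_raises(self):
        df, _ = records([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            wilcoxon_geneset(df, ["nonexistent", "also_missing"], "burst_size")

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        df, sig = records(rng.normal(1, 0.3, 8), rng.normal(0, 0.3, 30))
        p_raw = wilcoxon_geneset(df, sig, "burst_size").pvalue
        df2 = df.copy()
        df2["log2fc_burst_size"] = np.expm1(df2["log2fc_burst_size"] * 3.0)
        assert wilcoxon_geneset(df2, sig, "burst_size").pvalue == pytest.approx(p_raw)

    def test_exact_and_asymptotic_agree_at_n20(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=20)
        df, sig = records(vals[:8] + 0.5, vals[8:])
        from scipy.stats import mannwhitneyu

        x = df.loc[df.gene_id.isin(sig), "log2fc_burst_size"]
        y = df.loc[~df.gene_id.isin(sig), "log2fc_burst_size"]
        p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        p_asym = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_asym) / p_exact < 0.10

    def test_unknown_quantity_rejected(self):
        df, sig = records([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(KeyError):
            wilcoxon_geneset(df, sig, "nonsense")


@pytest.fixture(scope="module")
def gene_counts():
    rates = TelegraphRates(k_on=0.05, k_off=0.5, k_eject=3.0, k_decay=0.02)
    up = TelegraphRates(k_on=0.05, k_off=0.5, k_eject=9.0, k_decay=0.02)
    mk = lambda r, seed: betapoisson_counts(
        SimulationConfig(rates=r, n_alleles=2, n_cells=800, seed=seed)
    )
    treated = {"sig1": mk(up, 1), "sig2": mk(up, 2), "bg1": mk(rates, 3),
               "bg2": mk(rates, 4), "bg3": mk(rates, 5)}
    control = {g: mk(rates, 10 + i) for i, g in enumerate(treated)}
    hl = pd.Series(np.log(2) / 0.02, index=list(treated))
    return treated, control, hl


class TestPloidySensitivity:

    def test_baseline_ploidy_reproduces_standard_pipeline(self, gene_counts):
        treated, control, hl = gene_counts
        kwargs = dict(n_steps=300, n_burn=150)
        summary, details = ploidy_sensitivity(
            treated, control, hl, signature=["sig1", "sig2"],
            allele_grid=(2,), seed=5, **kwargs,
        )
        direct = fit_gene_table(treated, hl, condition="treated", n_alleles=2, seed=5, **kwargs)
        pd.testing.assert_frame_equal(details[2]["fits_treated"], direct)

    def test_frequency_shifts_monotonically_with_ploidy(self, gene_counts):
        treated, control, hl = gene_counts
        _, details = ploidy_sensitivity(
            {"bg1": treated["bg1"]}, {"bg1": control["bg1"]}, hl,
            signature=["bg1"], allele_grid=(2, 4, 8), seed=9,
            quantities=(), n_steps=1200, n_burn=400,
        )
        freqs = [
            details[p]["fits_treated"]["frequency_median"].iloc[0] for p in (2, 4, 8)
        ]
        # spreading fixed counts over more alleles implies rarer per-allele bursts
        assert freqs[0] > freqs[1] > freqs[2]
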