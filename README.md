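# burstkit

Per-gene inference of transcriptional-bursting kinetics from single-cell
RNA-seq count histograms, and analysis of how a treatment reshapes bursting
and gene–gene co-expression.

The motivating biology: cancer cells that keep proliferating after
chemotherapy upregulate an interferon-signature gene set (the U-ISGF3-related
genes, e.g. STAT1, IRF7, OASL).  The question a bursting analysis answers is
*how* that upregulation happens — do these genes fire bursts more often
(frequency, the ON rate `k_on`), or produce more mRNA per burst (burst size,
`k_eject/k_off`)?  burstkit provides the full workflow for that question:
quality filtering, Bayesian telegraph-model fits per gene, two-condition
fold-change comparison with a rank-sum test, ploidy-sensitivity refits, and
co-expression correlation matrices with dendrogram-order transfer — plus a
synthetic-study generator with complete ground truth for validating every
stage.

## The model

The two-state telegraph model: a promoter switches OFF→ON at `k_on` and
ON→OFF at `k_off`; while ON it emits mRNA at `k_eject`; transcripts decay at
`k_decay` (fixed per gene from measured half-lives, `k_decay = ln2 / t½`,
which puts all rates in units of min⁻¹).  The stationary mRNA count of one
allele is Beta-Poisson:

    P(n) = ∫₀¹ Pois(n; λp) Beta(p; a, b) dp ,   a = k_on/k_decay,
                                                b = k_off/k_decay,
                                                λ = k_eject/k_decay,

convolved over alleles (diploid by default).  Fitting is statsmodels-style:
`TelegraphModel(counts, k_decay, n_alleles).fit()` runs Metropolis-Hastings
over log10 rates and returns a `TelegraphResults` with posterior medians and
MADs of `k_on`, `k_off`, `k_eject`, burst size and frequency, diagnostics,
`summary()`, posterior-predictive and simulation methods.  A fit passes
quality control iff MAD/median < 0.75 for both `k_on` and burst size and
mean expression > 0.01.

## Worked example

```sh
burstkit simulate --out demo/study --seed 1 --n-background 60 --n-signature 12 --n-cells 800
burstkit fit      --study demo/study --out demo/fits --seed 1 --n-steps 1000 --n-burn 400
burstkit compare  --fits demo/fits/fits.tsv --study demo/study --out demo/cmp
```

which prints:

```
wrote study to demo/study: 2 conditions, 82 genes (12 signature), 800 cells each; burst multiplier 3.0
fitted 72 genes x 2 conditions; QC pass rate 1.00; wrote demo/fits/fits.tsv
expression: signature median log2FC +1.600 vs background +0.003; Wilcoxon p = 5.57e-08 (asymptotic)
frequency: signature median log2FC +0.045 vs background -0.036; Wilcoxon p = 0.634 (asymptotic)
burst_size: signature median log2FC +1.571 vs background +0.060; Wilcoxon p = 0.000136 (asymptotic)
```

Reading the numbers: the generator tripled the signature genes' burst size in
the treated condition, and the fits recover that — the signature's median
log2 fold change of burst size (+1.571) and of expression (+1.600) sit at
log2 3 ≈ 1.585, and the rank-sum test separates signature from background for
burst size (p = 1.4e-4) and expression, but **not** for frequency
(p = 0.63, median ≈ 0): the upregulation is carried by burst size, not burst
frequency.  `demo/cmp/fold_changes.tsv` holds the per-gene values,
`comparisons.json` the tests.  `burstkit coexpress` adds the per-condition
correlation matrices in the treated-derived gene order, and `burstkit
run-all` chains all stages.  Equivalent library entry points live in
`burstkit.pipeline` (`fit_study`, `compare_fits`, `coexpress_study`).

## Layout

| module | contents |
| --- | --- |
| `burstkit.core` | rates, Beta-Poisson closed form + truncated-CME oracle, moments, allele convolution, burst statistics |
| `burstkit.simulate` | exact Gillespie and stationary Beta-Poisson samplers |
| `burstkit.inference` | `TelegraphModel` / `TelegraphResults`, MH sampler, QC filter, per-gene fit tables |
| `burstkit.preprocess` | cell/gene filters (strict printed thresholds), log-normalization, MTX study I/O |
| `burstkit.compare` | log2 fold changes, signature-vs-background Wilcoxon, ploidy sensitivity |
| `burstkit.coexpression` | Pearson matrices, hierarchical ordering + transfer, block scores |
| `burstkit.synthetic` | ground-truth two-condition study generator |
| `burstkit.pipeline`, `burstkit.cli` | workflow composition and the `burstkit` command |
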