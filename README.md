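# scherit

Cell-type-resolved partitioned heritability from single-cell expression.

Single-cell RNA-seq tells you what each cell type expresses; a GWAS tells
you where a trait's inherited risk sits in the genome. This package
connects the two: it builds, for every cell type, the set of genes most
specifically expressed there, annotates GWAS SNPs falling within a window
around those genes, and asks — by stratified LD score regression on
summary statistics — whether that cell type's annotation carries more
per-SNP heritability than the genome-wide average. It was built around
the esophageal setting (Barrett's esophagus and esophageal
adenocarcinoma, where the question is which cell types — intestinal
metaplasia cells, fibroblast and endothelial subtypes, immune cells —
mediate germline risk), but nothing in the code is tissue-specific.

The package is an analysis project: the library under `src/scherit/`
holds every computational step, the numbered drivers under `analysis/`
run the study on synthetic data with known ground truth, and
`scripts/acceptance.py` recomputes the headline numbers from scratch.

## The model

For SNP j with GWAS sample size N and association statistic χ²ⱼ,
stratified LD score regression fits

    E[χ²ⱼ] = N · Σ_C τ_C · ℓ(j, C) + intercept,

where ℓ(j, C) = Σ_{k∈C} r²(j, k) is the partitioned LD score of SNP j
against annotation category C and τ_C is the per-SNP heritability
contributed by membership in C. Categories are the all-SNP base plus one
annotation per cell type (SNPs within gene body ± 100 kb of the cell
type's top-15% most specifically expressed genes; specificity of gene g
in type t is its expression in t divided by its summed expression over
all types). The fit is weighted least squares with weights 1/max(1,
ℓ_base); standard errors of every reported scalar come from a
delete-one-block jackknife over contiguous SNP blocks in genomic order.
A category's fold enrichment is its share of h² over its share of SNPs;
the cell-type test is the one-sided p on τ_C, Benjamini–Hochberg-adjusted
across cell types.

Supporting single-cell statistics implemented alongside: staged QC
(minimum detected genes, 3-MAD outlier trim on counts and detected
genes, a 30% mitochondrial cap, then a per-cell-type top-15%
mitochondrial cut), log-normalization, marker statistics (logFC and the
pct.ratio cluster-specificity measure), a smoothed-difference PC
retention rule, binned signature-minus-control module scores with
cell-cycle phase calls and the relative proliferation index
(#S + #G2M)/#G1, and expression-derived SCNA profiles (reference-centred,
clipped, 150-gene sliding window along genomic order, centromere marks).

Because the motivating study's data are access-controlled, the
`scherit.simulate` module generates every input with planted ground
truth: clustered negative-binomial counts with fold-8 markers, an AR(1)
latent-Gaussian LD-block genotype panel, and GWAS summary statistics
whose per-SNP effect variance is enriched by a known fold inside a known
annotation.

## Worked example

```python
from scherit import (LdSimConfig, GwasSimConfig, simulate_ld_reference,
                     make_block_annotation, simulate_gwas,
                     compute_ld_scores, stratified_ldsc)

panel = simulate_ld_reference(LdSimConfig(
    n_individuals=500, n_blocks=200, block_size=20, seed=7))
annot = make_block_annotation(panel, category_fraction=0.1, seed=7)
sumstats = simulate_gwas(panel, annot, GwasSimConfig(
    h2_total=0.4, enriched_category="CT", true_enrichment=5.0,
    gwas_n=5000, seed=11))
ldsc = compute_ld_scores(panel, annot)
res = stratified_ldsc(sumstats, ldsc, annot, n_blocks=200)
print(res.table.loc["CT", ["enrichment", "enrichment_se", "z", "p"]])
```

prints

```
enrichment       3.8376
enrichment_se    0.7859
z                2.6740
p                0.0037
```

The planted architecture concentrates effect variance fivefold in the
"CT" category covering 10% of SNPs, so its true fold enrichment is
5/(1 + 4·0.1) ≈ 3.57; the fit recovers ≈ 3.84 ± 0.79 with a clearly
positive coefficient (one-sided p = 0.004). Running the numbered drivers
in `analysis/` reproduces the full study: data generation, QC and gene
sets (planted-marker recall 1.00), cell-cycle indices (1.50
proliferative vs 0.11 quiescent cluster), SCNA profiles (plateau ≈ 0.48
on a planted +0.5 gain), and the per-cell-type enrichment table in which
the planted cell type attains the smallest p in 10/10 GWAS replicates.

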