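# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `scherit`, and says what the passing tests do and
do not establish about real data.

## Stratified LD score regression

The estimator fits, over SNPs j,

    E[chi^2_j] = N_j * sum_C tau_C * l(j, C) + intercept

by weighted least squares, with l(j, C) the partitioned LD score
(sum of squared dosage correlation between j and every SNP annotated to
category C) and tau_C the per-SNP heritability contribution of C. The
category set is always the all-ones base plus the annotations under
test; the cell-type test fits base + one cell type at a time and reports
the one-sided p on that cell type's tau (H1: tau_C > 0), BH-adjusted
across cell types within a trait.

Derived quantities, all with block-jackknife SEs:
h2(C) = sum_{j in C} sum_{C'} tau_{C'} a(j, C') (computed via the
category overlap matrix a^T a), prop_h2 = h2(C)/h2(base), and fold
enrichment = prop_h2 / (M_C / M). The base category's enrichment is
identically 1 for any fitted tau — an algebraic identity the tests
assert.

Numerical choices:

* **Weights** are 1/max(1, l_base): the LD over-counting correction
  only. The full heteroskedasticity weighting of mature implementations
  is deliberately not reproduced; calibration is verified by simulation
  (type-I error, KS uniformity) rather than by matching an external
  binary.
* **r^2 estimator**: squared Pearson correlation of dosages, optionally
  (and by default) with the small-sample correction
  r2 - (1 - r2)/(n - 2). On the synthetic genome LD scores are computed
  over whole chromosomes (`ld_window_bp=None`), which is exact because
  blocks are independent by construction; for larger inputs a finite
  window is supported.
* **Jackknife**: delete-one-block over contiguous SNP blocks in genomic
  order (default 200 blocks), applied to every reported scalar, with
  SE^2 = (B-1)/B * sum (theta_i - mean)^2. On noise-free input the SEs
  collapse to numerical zero. Jackknife blocks must be at least as long
  as the LD range; in the simulation experiments they coincide with the
  simulated LD blocks.
* **Intercept** is fitted by default (free confounding/misspecification
  absorber); `fit_intercept=False` constrains it to zero.
* Rank-deficient designs (duplicate or collinear categories) raise with
  the offending pairs listed; degenerate SEs of exactly zero propagate
  as inf/nan z rather than being masked.
* Alleles in summary statistics are checked against the variant table
  (`scherit.io.check_alleles` reports the mismatch rate) but never
  flipped: chi-square is sign-free.

### A calibration lesson baked into the study conditions

With the trait architecture uniform (no enrichment), tau_hat for a
category is unbiased, but the coefficient z = tau_hat/SE_hat is
left-skewed when the category covers only a handful of long LD blocks:
the estimate and its jackknife SE then ride on the same few block-level
effect draws, so "hot" draws inflate both and positive z is deflated
more than negative. This is a small-numbers effect of the category's
independent LD units, not an estimator bug — it persists when regressing
on near-population LD scores from a 20,000-individual panel. The
synthetic genome therefore uses many short blocks (200 blocks of 10-20
SNPs; a 10% category spans ~20 independent blocks), which is also the
realistic regime: a real gene-set annotation touches hundreds of loci.
Under these conditions the null one-sided p-values are uniform (KS
p = 0.14 at 200 tests) and the empirical type-I error at 0.05 sits
inside its binomial band.

The fold-enrichment point estimate is a ratio and is right-skewed at
desk scale (median estimates above the truth with correspondingly large
jackknife SEs); the 2-SE coverage of the truth is the calibrated
statement, and it holds in 20/20 seeded replicates under the planted
fold-5 architecture.

## Gene sets, specificity and annotations

Specificity of gene g in cell type t is its per-type expression divided
by the sum of that expression over all types; rows sum to 1 and genes
with zero expression everywhere are dropped. "Expression" defaults to
the mean log-normalized value per type (`mean-lognorm`), with
`mean-counts` and `summed-counts` as switches — the aggregation is a
genuine free choice and the default is the one that matches the
log-scale processing stream. Each cell type's gene set is the top 15%
most specific genes (ceiling of 0.15 * G), ties broken lexicographically
by gene id for determinism (`keep_ties=True` keeps all tied genes).

SNP annotation: a SNP belongs to a set's category iff its position lies
within [start - W, end + W] of any gene of the set on the same
chromosome, 1-based inclusive on both ends, W = 100 kb by default. On
the compressed synthetic genome (1 kb SNP spacing, 1 kb genes) the
window scales down with the geometry — the end-to-end experiments use
±2 kb, which plays the role the 100 kb window plays at genome scale.
BED input is converted from 0-based half-open to 1-based inclusive, and
the conversion is tested.

## Single-cell statistics

* **QC** is a staged filter: (1) fewer than `min_genes` detected genes
  (1000 by default; 500 where a wider spectrum of cells should be kept —
  the synthetic libraries are sparser than real 10x data, so the
  experiments use the lower setting); (2) median ± 3 MAD on total counts
  and on detected genes, both tails, MAD unscaled (no 1.4826 factor),
  deviations exactly at the bound kept; (3) mitochondrial fraction above
  30%; (4) within each cell type, the top 15% of surviving cells by
  mitochondrial fraction (floor of the count). Stage 4 needs labels and
  is skipped (and flagged) on re-runs, making the filter idempotent
  through stages 1-3 on the data it produces. Each stage's removal count
  is reported; an emptied matrix raises naming the stage.
* **Normalization**: x = ln(1 + scale * count/total), scale 1e4.
* **Marker statistics**: per (cluster, gene), logFC is the natural log
  of (mean expm1(x) + 1) in-cluster over the same quantity in all other
  cells; pct_in/pct_out are nonzero fractions; pct.ratio = pct_in /
  pct_out with +inf for cluster-exclusive genes so they rank above every
  finite ratio. The 30% / 0.1 thresholds are pre-filters, not
  significance tests: label permutation does not empty the passing set
  (noise alone crosses logFC 0.1), but it collapses the planted markers'
  top-of-ranking position to chance recall — the ranking, not the
  binary pass, carries the signal, and that is what the tests assert.
* **PC retention**: consecutive differences of the percent-variance
  sequence, smoothed by a centered rolling mean of 2*halfwidth + 1
  points (window shrinking at the edges); the first index whose smoothed
  difference drops below 0.02 is the number of PCs kept, all of them if
  none does.
* **Module scores** (Tirosh-style): genes binned into 25 equal-size bins
  by average expression; each signature gene contributes `n_ctrl`
  seeded draws (with replacement) of control genes from its bin; score =
  mean signature minus mean control pool per cell. A Pearson-correlation
  variant exists behind `method="correlation"` but is not the default.
  Phase call: G1 iff both S and G2/M scores are at or below 0, else the
  larger score, exact ties to S. The relative proliferation index is
  (#S + #G2M)/#G1 per cluster, +inf with a flag when G1 is empty.
* **SCNA profiles**: drop genes below `min_mean_expr` (default 0.1);
  center each gene on its reference-cell mean; clip to ±3; order genes
  by (chromosome, start); smooth per chromosome with a centered moving
  average of width 150 over gene order, the window shrinking
  symmetrically at chromosome edges (no padding, never spanning
  chromosomes; width 1 is the identity); subtract each cell's median.
  Centromeres are marked at the last retained gene starting before the
  centromere position, or the first retained gene after it as a proxy.
  Defaults for `min_mean_expr` and `clip` follow common practice for
  expression-based SCNA smoothing; both are explicit parameters. HMM
  segmentation, denoising and discrete copy-number calls are out of
  scope — the module produces the smoothed profile matrix only.

## Synthetic study conditions

The generators define the conditions everything is tested under:

* **Counts**: NB(mu, theta) with baseline mean 0.5 and dispersion
  theta = 2; 5 cell types x 200 cells, 2000 genes, 50 markers per type
  with fold 8 in the home type; 20 mitochondrial genes whose means are
  set so each cell's expected mitochondrial fraction is a uniform draw
  from [0.02, 0.10]. Empirical marker fold converges to the target
  (rel. error < 10% at 500 cells/type).
* **Genotypes**: per block, a latent Gaussian AR(1) field
  (corr rho^|j-k|, rho = 0.9) thresholded at the per-SNP MAF quantile
  (MAF ~ U(0.05, 0.5)) into two haplotypes summed to dosage. Blocks are
  independent; realized dosage r is attenuated relative to the latent
  rho, and the tests calibrate against a 10^6-individual Monte-Carlo
  oracle of the post-thresholding correlation rather than against rho.
  Monomorphic draws abort rather than being silently patched.
* **GWAS**: effects on standardized genotypes, beta_j ~ N(0, sigma^2_j)
  with sigma^2_j proportional to 1 + (e - 1) a_j and scaled to h2; the
  category's realized share of effect variance is e*f/(1 + (e-1)f)
  exactly, by construction. The phenotype is y = X_std beta + eps on a
  fresh cohort drawn from the same LD law (reusing the panel is a flag
  for small fixtures), and Z is the marginal regression t-statistic.
  Headline conditions: h2 = 0.4, e = 5, N = 5000, M = 4000, category
  fraction 0.1 for recovery; e = 1, h2 = 0.3, N = 2000, M = 2000 for
  null calibration (200 tests).
* All randomness flows from one master seed through named substreams
  (sc / panel / gwas / gwas_cohort), so stages regenerate independently
  and bit-identically.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, read-level noise (no FASTQ), MAF- or LD-dependent genetic
architectures, population stratification, and allele-coding ambiguities.
Passing tests therefore demonstrate that the implementations compute
their defined statistics correctly and that the estimator is calibrated
under its own generative model — not that the pipeline is robust to the
failure modes of real single-cell or GWAS data.

## Problem sizes

The analysis drivers and the acceptance script run at desk scale on one
CPU: 1000 cells x 2000 genes for the expression stages; 4000 SNPs x 500
panel individuals with 5000-individual GWAS cohorts (20 replicates) for
enrichment recovery; 2000 SNPs with 2000-individual cohorts for the 200
null tests; 2000 SNPs / 600 genes for the end-to-end cell-type ranking.
These sizes were chosen so the whole study reruns in minutes while
keeping enough independent LD blocks for calibrated jackknife inference.
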