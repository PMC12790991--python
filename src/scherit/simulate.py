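"""Synthetic-data generators with known ground truth.

Three simulators provide the raw material for the whole pipeline:

* :func:`simulate_sc_counts` — clustered negative-binomial single-cell
  counts with planted cell-type-specific marker genes and a designated
  mitochondrial gene block, emulating a 10x-style count matrix.
* :func:`simulate_ld_reference` — a genotype reference panel with block
  LD structure (latent AR(1) Gaussian, thresholded at MAF-matched
  quantiles into two haplotypes).
* :func:`simulate_gwas` — GWAS summary statistics (Z per SNP) under a
  stratified per-SNP heritability model in which effect variance inside a
  chosen annotation category exceeds the genome-wide average by a known
  fold.

All randomness flows from a single integer seed through named substreams
so each stage can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import stats

from .herit import AnnotationMatrix


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


_STREAMS = {"sc": 11, "panel": 23, "gwas": 37, "gwas_cohort": 41, "genes": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    if seed < 0:
        raise ConfigError("seed must be a non-negative integer")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

_TISSUES = ("esophagus", "fundus", "BE", "EAC")


@dataclass
class ScSimConfig:
    """Parameters of the clustered single-cell count simulator.

    ``marker_fold`` multiplies the NB mean of a marker gene in cells of
    its home type; ``nb_dispersion`` is the NB size parameter theta
    (variance = mu + mu^2/theta). ``mito_fraction_range`` gives the
    per-cell target fraction of counts landing in mitochondrial genes.
    """

    n_cell_types: int = 5
    cells_per_type: int = 200
    n_genes: int = 2000
    n_markers_per_type: int = 50
    marker_fold: float = 8.0
    baseline_mean: float = 0.5
    nb_dispersion: float = 2.0
    mito_fraction_range: tuple[float, float] = (0.02, 0.10)
    n_mito_genes: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cell_types", "cells_per_type", "n_genes",
                     "n_markers_per_type", "n_mito_genes"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_markers_per_type * self.n_cell_types + self.n_mito_genes > self.n_genes:
            raise ConfigError(
                "n_genes too small: n_markers_per_type * n_cell_types + "
                "n_mito_genes must not exceed n_genes")
        if not self.marker_fold >= 1:
            raise ConfigError("marker_fold must be >= 1")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ConfigError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")


def simulate_sc_counts(cfg: ScSimConfig) -> tuple[ad.AnnData, dict[str, list[str]]]:
    """Draw a cells x genes count matrix with planted markers.

    Returns an :class:`anndata.AnnData` (``X`` integer counts, ``obs``
    carrying ``cell_type``/``sample``/``tissue``, ``var`` carrying
    ``is_mito``) and the ground-truth map ``cell_type -> marker genes``.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "sc")
    T, C, G = cfg.n_cell_types, cfg.cells_per_type, cfg.n_genes
    n_cells = T * C

    gene_ids = [f"gene{i:05d}" for i in range(G - cfg.n_mito_genes)]
    gene_ids += [f"MT-{i:03d}" for i in range(cfg.n_mito_genes)]
    is_mito = np.zeros(G, dtype=bool)
    is_mito[G - cfg.n_mito_genes:] = True

    cell_types = np.repeat([f"type{t:02d}" for t in range(T)], C)
    cell_ids = [f"cell{i:06d}" for i in range(n_cells)]

    mean = np.full((n_cells, G), cfg.baseline_mean)
    marker_map: dict[str, list[str]] = {}
    for t in range(T):
        lo = t * cfg.n_markers_per_type
        hi = lo + cfg.n_markers_per_type
        marker_map[f"type{t:02d}"] = gene_ids[lo:hi]
        mean[t * C:(t + 1) * C, lo:hi] *= cfg.marker_fold

    # mitochondrial means chosen so the expected mito share of each cell
    # equals a per-cell draw from mito_fraction_range
    frac = rng.uniform(*cfg.mito_fraction_range, size=n_cells)
    non_mito_sum = mean[:, ~is_mito].sum(axis=1)
    with np.errstate(divide="ignore"):
        mito_mean = frac * non_mito_sum / ((1.0 - frac) * cfg.n_mito_genes)
    mean[:, is_mito] = mito_mean[:, None]

    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean)).astype(np.int32)

    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical(cell_types),
            "sample": [f"S{t[4:]}" for t in cell_types],
            "tissue": [_TISSUES[int(t[4:]) % len(_TISSUES)] for t in cell_types],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame({"is_mito": is_mito}, index=pd.Index(gene_ids, name="gene_id"))
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["marker_map"] = {k: list(v) for k, v in marker_map.items()}
    return adata, marker_map


# ---------------------------------------------------------------------------
# LD reference panel
# ---------------------------------------------------------------------------


@dataclass
class LdSimConfig:
    """Block-LD genotype model: latent AR(1) Gaussian per block
    (corr(j,k) = rho^|j-k| within a block, 0 across blocks), thresholded
    at the per-SNP MAF quantile to yield two haplotypes per individual.
    The realized dosage correlation is attenuated relative to the latent
    rho by the dichotomisation.
    """

    n_individuals: int = 500
    n_blocks: int = 40
    block_size: int = 50
    within_block_corr: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    bp_per_snp: int = 1000
    n_chromosomes: int = 1
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.block_size

    def validate(self) -> None:
        for name in ("n_individuals", "n_blocks", "block_size", "bp_per_snp",
                     "n_chromosomes"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 <= self.within_block_corr < 1:
            raise ConfigError("within_block_corr must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must be an interval in (0, 0.5]")
        if self.n_chromosomes > self.n_blocks:
            raise ConfigError("n_chromosomes must not exceed n_blocks")


@dataclass
class GenotypePanel:
    """Reference genotypes: individuals x SNPs dosages in {0,1,2} plus a
    variant table sorted by (chromosome, position)."""

    dosages: np.ndarray
    variants: pd.DataFrame
    config: LdSimConfig | None = None
    block_index: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


def _draw_latent_ar1(rng: np.random.Generator, n_rows: int, cfg: LdSimConfig) -> np.ndarray:
    """Latent Gaussian haplotype field, AR(1) within each block."""
    M = cfg.n_snps
    rho = cfg.within_block_corr
    z = rng.standard_normal((n_rows, M))
    scale = np.sqrt(1.0 - rho ** 2)
    for b in range(cfg.n_blocks):
        s = b * cfg.block_size
        for j in range(s + 1, s + cfg.block_size):
            z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
    return z


def _dosages_from_latent(z: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    n2 = z.shape[0]
    assert n2 % 2 == 0
    hap = (z < thresholds[None, :]).astype(np.int8)
    n = n2 // 2
    return hap[:n] + hap[n:]


def _variant_table(cfg: LdSimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    M = cfg.n_snps
    block_index = np.repeat(np.arange(cfg.n_blocks), cfg.block_size)
    chrom_of_block = np.array_split(np.arange(cfg.n_blocks), cfg.n_chromosomes)
    chrom = np.empty(M, dtype=object)
    pos = np.empty(M, dtype=np.int64)
    for c, blocks in enumerate(chrom_of_block):
        mask = np.isin(block_index, blocks)
        chrom[mask] = str(c + 1)
        pos[mask] = (np.arange(mask.sum()) + 1) * cfg.bp_per_snp
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1:06d}" for i in range(M)],
            "CHR": chrom,
            "POS": pos,
            "A1": "A",
            "A2": "G",
        }
    )
    return variants, block_index


def simulate_ld_reference(cfg: LdSimConfig) -> GenotypePanel:
    """Draw the genotype reference panel; deterministic under the seed."""
    cfg.validate()
    rng = _rng(cfg.seed, "panel")
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    thresholds = stats.norm.ppf(mafs)
    z = _draw_latent_ar1(rng, 2 * cfg.n_individuals, cfg)
    dosages = _dosages_from_latent(z, thresholds)
    if (dosages.std(axis=0) == 0).any():
        bad = int((dosages.std(axis=0) == 0).sum())
        raise RuntimeError(
            f"{bad} monomorphic SNP(s) drawn; increase n_individuals or the "
            "lower end of maf_range")
    variants, block_index = _variant_table(cfg)
    return GenotypePanel(dosages=dosages, variants=variants, config=cfg,
                         block_index=block_index)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


@dataclass
class GwasSimConfig:
    """Stratified heritability architecture for the summary-statistic
    simulator: per-SNP effect variance (on standardized genotypes) is
    proportional to ``1 + (true_enrichment - 1) * a_j`` for membership
    ``a_j`` in ``enriched_category``, scaled to total ``h2_total``.
    """

    h2_total: float = 0.4
    enriched_category: str = "base"
    true_enrichment: float = 1.0
    gwas_n: int = 5000
    reuse_panel_cohort: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.h2_total <= 1:
            raise ConfigError("h2_total must be in [0, 1]")
        if self.true_enrichment < 0:
            raise ConfigError("true_enrichment must be >= 0")
        if int(self.gwas_n) < 3:
            raise ConfigError("gwas_n must be >= 3")


def per_snp_heritability(annot: AnnotationMatrix, cfg: GwasSimConfig) -> np.ndarray:
    """Exact per-SNP effect variances sigma^2_j implied by the config.

    By construction the category's share of total heritability equals
    e*f / (1 + (e-1)*f) for enrichment fold e and SNP fraction f.
    """
    cfg.validate()
    if cfg.enriched_category not in annot.categories:
        raise ConfigError(
            f"enriched_category {cfg.enriched_category!r} absent from annotation "
            f"(has {annot.categories})")
    a = annot.matrix[:, annot.categories.index(cfg.enriched_category)].astype(float)
    sigma2 = 1.0 + (cfg.true_enrichment - 1.0) * a
    total = sigma2.sum()
    if total <= 0:
        return np.zeros_like(sigma2)
    return cfg.h2_total * sigma2 / total


def simulate_gwas(panel: GenotypePanel, annot: AnnotationMatrix,
                  cfg: GwasSimConfig) -> pd.DataFrame:
    """Simulate marginal association Z statistics on a fresh cohort.

    The phenotype is ``y = X_std beta + eps`` with ``beta_j ~
    N(0, sigma^2_j)`` on standardized genotypes and ``Var(eps) = 1 -
    h2_total``; the cohort is drawn from the same LD law as the panel
    (or the panel itself when ``reuse_panel_cohort``). Returns the
    summary-statistic table with columns ``SNP A1 A2 N Z``.
    """
    cfg.validate()
    if list(annot.snps["SNP"]) != list(panel.variants["SNP"]):
        raise ValueError("annotation SNPs must align with the panel variant table")
    sigma2 = per_snp_heritability(annot, cfg)
    rng = _rng(cfg.seed, "gwas")
    beta = rng.normal(0.0, np.sqrt(sigma2))

    if cfg.reuse_panel_cohort:
        X = panel.dosages.astype(float)
        n = X.shape[0]
    else:
        if panel.config is None:
            raise ValueError("panel has no LD config; cannot draw a fresh cohort "
                             "(set reuse_panel_cohort=True)")
        n = int(cfg.gwas_n)
        cohort_rng = _rng(cfg.seed, "gwas_cohort")
        ldcfg = panel.config
        mafs = _rng(ldcfg.seed, "panel").uniform(*ldcfg.maf_range, size=ldcfg.n_snps)
        thresholds = stats.norm.ppf(mafs)
        z = _draw_latent_ar1(cohort_rng, 2 * n, ldcfg)
        X = _dosages_from_latent(z, thresholds).astype(float)

    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        # monomorphic draw in the cohort: that SNP carries no signal and an
        # undefined marginal statistic; give it Z = 0
        sd = np.where(sd == 0, np.inf, sd)
    Xs = Xc / sd
    y = Xs @ beta + rng.normal(0.0, np.sqrt(max(0.0, 1.0 - cfg.h2_total)), size=n)

    yc = y - y.mean()
    ssy = float(yc @ yc)
    r = (Xc.T @ yc) / np.sqrt((Xc ** 2).sum(axis=0) * ssy)
    r = np.clip(np.nan_to_num(r), -0.999999, 0.999999)
    zstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))

    return pd.DataFrame(
        {
            "SNP": panel.variants["SNP"].to_numpy(),
            "A1": panel.variants["A1"].to_numpy(),
            "A2": panel.variants["A2"].to_numpy(),
            "N": n,
            "Z": zstat,
        }
    )


# ---------------------------------------------------------------------------
# auxiliary ground-truth structures
# ---------------------------------------------------------------------------


def make_block_annotation(panel: GenotypePanel, category_fraction: float,
                          name: str = "CT", seed: int = 0) -> AnnotationMatrix:
    """Binary category covering whole LD blocks (about ``category_fraction``
    of SNPs), plus the all-ones base category.

    Annotating whole blocks keeps category membership aligned with the LD
    structure, as gene windows are in real annotations.
    """
    if panel.block_index is None or panel.config is None:
        raise ValueError("panel lacks block structure")
    if not 0 < category_fraction <= 1:
        raise ConfigError("category_fraction must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    n_blocks = panel.config.n_blocks
    n_pick = max(1, int(round(category_fraction * n_blocks)))
    picked = rng.choice(n_blocks, size=n_pick, replace=False)
    a = np.isin(panel.block_index, picked).astype(np.int8)
    matrix = np.column_stack([np.ones(panel.n_snps, dtype=np.int8), a])
    return AnnotationMatrix(
        snps=panel.variants[["SNP", "CHR", "POS"]].rename(columns={"POS": "BP"}).copy(),
        matrix=matrix,
        categories=["base", name],
    )


def simulate_gene_coordinates(gene_ids, chrom_lengths: dict[str, int],
                              gene_length: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Place genes uniformly on synthetic chromosomes (1-based inclusive
    coordinates), for bridging expression gene sets to SNP positions."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 131]))
    chroms = list(chrom_lengths)
    assign = rng.choice(len(chroms), size=len(gene_ids))
    starts = np.empty(len(gene_ids), dtype=np.int64)
    for i, c in enumerate(assign):
        starts[i] = rng.integers(1, max(2, chrom_lengths[chroms[c]] - gene_length))
    coords = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "chrom": [chroms[c] for c in assign],
            "start": starts,
            "end": starts + gene_length - 1,
            "strand": rng.choice(["+", "-"], size=len(gene_ids)),
        }
    )
    return coords.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
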