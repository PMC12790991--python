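"""Partitioned heritability by stratified LD score regression.

The model: for SNP j with GWAS sample size N_j and association statistic
chi^2_j,

    E[chi^2_j] = N_j * sum_C tau_C * l(j, C) + intercept,

where l(j, C) is the partitioned LD score of SNP j with respect to
category C (sum of squared LD with all annotated SNPs) and tau_C is the
per-SNP heritability contribution of category C. Categories are built
from gene sets by annotating SNPs within a window around each gene's
body. Standard errors of every reported scalar come from a delete-one
block jackknife over contiguous SNP blocks in genomic order. Fold
enrichment of a category is its share of h2 divided by its share of
SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationMatrix:
    """SNP x category binary membership, base (all-ones) category first."""

    snps: pd.DataFrame          # columns SNP, CHR, BP
    matrix: np.ndarray          # M x C, entries in {0, 1}
    categories: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.snps), len(self.categories)):
            raise ValueError("annotation matrix shape does not match SNPs/categories")
        if "base" not in self.categories:
            raise ValueError("annotation must include the base category")
        base = self.matrix[:, self.categories.index("base")]
        if not np.all(base == 1):
            raise ValueError("base category must be all ones")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def m_c(self) -> pd.Series:
        """Number of annotated SNPs per category."""
        return pd.Series(self.matrix.sum(axis=0), index=self.categories, name="M_C")

    def subset_categories(self, names: list[str]) -> "AnnotationMatrix":
        idx = [self.categories.index(n) for n in names]
        return AnnotationMatrix(self.snps, self.matrix[:, idx], list(names))

    def subset_snps(self, snp_ids) -> "AnnotationMatrix":
        order = self.snps.set_index("SNP").index.get_indexer(snp_ids)
        if (order < 0).any():
            raise KeyError("requested SNPs absent from annotation")
        return AnnotationMatrix(self.snps.iloc[order].reset_index(drop=True),
                                self.matrix[order], list(self.categories))


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + 1:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def build_annotation(gene_sets: dict[str, list[str]], coords: pd.DataFrame,
                     variants: pd.DataFrame, window_bp: int = 100_000) -> AnnotationMatrix:
    """Annotate SNPs falling within ``gene body +/- window_bp`` of any gene
    of each set (1-based inclusive on both ends).

    ``coords`` has columns gene/chrom/start/end; ``variants`` has columns
    SNP/CHR/POS. Genes missing from ``coords`` are dropped (counted in a
    warning); a category left empty after mapping is kept with M_C = 0.
    """
    coord_chroms = set(coords["chrom"].astype(str))
    var_chroms = set(variants["CHR"].astype(str))
    if not coord_chroms & var_chroms:
        raise ValueError(
            f"no shared chromosome naming between gene coordinates "
            f"({sorted(coord_chroms)[:5]}...) and variants ({sorted(var_chroms)[:5]}...)")

    snps = variants[["SNP", "CHR", "POS"]].rename(columns={"POS": "BP"}).reset_index(drop=True)
    M = len(snps)
    cols = [np.ones(M, dtype=np.int8)]
    names = ["base"]
    cix = coords.set_index("gene")
    for name, genes in gene_sets.items():
        missing = [g for g in genes if g not in cix.index]
        if missing:
            warnings.warn(
                f"gene set {name!r}: {len(missing)} gene(s) without coordinates dropped")
        sub = cix.loc[[g for g in genes if g in cix.index]]
        a = np.zeros(M, dtype=np.int8)
        for chrom, grp in sub.groupby("chrom", observed=True):
            starts = np.maximum(1, grp["start"].to_numpy() - window_bp)
            ends = grp["end"].to_numpy() + window_bp
            ms, me = _merge_intervals(starts, ends)
            mask = snps["CHR"].astype(str).to_numpy() == str(chrom)
            pos = snps.loc[mask, "BP"].to_numpy()
            k = np.searchsorted(ms, pos, side="right") - 1
            inside = (k >= 0) & (pos <= me[np.clip(k, 0, len(me) - 1)])
            a[np.flatnonzero(mask)[inside]] = 1
        if a.sum() == 0:
            warnings.warn(f"gene set {name!r} annotates no SNP (kept with M_C = 0)")
        cols.append(a)
        names.append(name)
    return AnnotationMatrix(snps=snps, matrix=np.column_stack(cols), categories=names)


# ---------------------------------------------------------------------------
# partitioned LD scores
# ---------------------------------------------------------------------------


@dataclass
class PartitionedLDScores:
    """Per-SNP sums of squared LD with annotated SNPs, one column per
    category; ``adjusted`` marks the small-sample-corrected r^2."""

    table: pd.DataFrame         # SNP, CHR, BP + one l column per category
    categories: list[str]
    adjusted: bool

    def values(self) -> np.ndarray:
        return self.table[self.categories].to_numpy(float)


def compute_ld_scores(panel, annot: AnnotationMatrix, ld_window_bp: int | None = None,
                      adjusted: bool = True) -> PartitionedLDScores:
    """Partitioned LD scores from panel dosages.

    r^2 is squared Pearson correlation of dosages; with ``adjusted`` the
    small-sample estimator ``r2 - (1 - r2)/(n - 2)`` is used. Pairs are
    summed over annotated SNPs on the same chromosome within
    ``ld_window_bp`` (``None`` = whole chromosome, exact for synthetic
    panels). Self-pairs are included when the SNP is annotated.
    """
    pv = panel.variants.set_index("SNP")
    order = pv.index.get_indexer(annot.snps["SNP"])
    if (order < 0).any():
        raise ValueError("panel must contain every annotation SNP")
    X = panel.dosages[:, order].astype(float)
    n = X.shape[0]
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("monomorphic SNP in panel; filter before computing LD scores")
    Xs = (X - X.mean(axis=0)) / sd
    r = (Xs.T @ Xs) / (n - 1)
    r2 = r ** 2
    if adjusted:
        r2 = r2 - (1.0 - r2) / (n - 2)

    chrom = annot.snps["CHR"].astype(str).to_numpy()
    bp = annot.snps["BP"].to_numpy()
    mask = chrom[:, None] == chrom[None, :]
    if ld_window_bp is not None:
        mask &= np.abs(bp[:, None] - bp[None, :]) <= ld_window_bp
    ell = (r2 * mask) @ annot.matrix.astype(float)

    table = annot.snps.copy()
    for i, c in enumerate(annot.categories):
        table[c] = ell[:, i]
    return PartitionedLDScores(table=table, categories=list(annot.categories),
                               adjusted=adjusted)


# ---------------------------------------------------------------------------
# stratified regression with block jackknife
# ---------------------------------------------------------------------------


@dataclass
class HeritabilityResult:
    """Per-category stratified-LDSC estimates.

    ``table`` is indexed by category with columns tau, tau_se, z, p, h2,
    prop_h2, prop_h2_se, prop_snps, enrichment, enrichment_se.
    """

    table: pd.DataFrame
    intercept: float
    intercept_se: float
    h2_total: float
    h2_total_se: float
    n_snps: int
    n_blocks: int


def _jackknife_se(estimates: np.ndarray) -> np.ndarray:
    """Delete-one-block jackknife SE from the B delete-block estimates."""
    B = estimates.shape[0]
    mean = estimates.mean(axis=0)
    return np.sqrt((B - 1) / B * ((estimates - mean) ** 2).sum(axis=0))


def stratified_ldsc(sumstats: pd.DataFrame, ldscores: PartitionedLDScores,
                    annot: AnnotationMatrix, n_blocks: int = 200,
                    fit_intercept: bool = True) -> HeritabilityResult:
    """Fit E[chi^2_j] = N_j sum_C tau_C l(j,C) + intercept by weighted
    least squares and jackknife every reported scalar over contiguous
    SNP blocks in genomic order.

    Weights are 1/max(1, l_base) (LD over-counting correction).
    h2(C) = sum_{j in C} sum_{C'} tau_{C'} a(j,C'); enrichment is the h2
    share over the SNP share, identically 1 for the base category.
    """
    merged = sumstats.merge(ldscores.table, on="SNP", how="inner")
    if len(merged) == 0:
        raise ValueError("no SNP shared between summary statistics and LD scores")
    merged = merged.sort_values(["CHR", "BP"], kind="stable").reset_index(drop=True)
    sub_annot = annot.subset_snps(merged["SNP"])
    cats = list(ldscores.categories)
    if not (2 <= n_blocks <= len(merged)):
        raise ValueError("n_blocks must be between 2 and the number of SNPs")

    ell = merged[cats].to_numpy(float)
    N = merged["N"].to_numpy(float)
    chi2 = merged["Z"].to_numpy(float) ** 2
    base_ix = cats.index("base")

    design = ell * N[:, None]
    if fit_intercept:
        design = np.column_stack([design, np.ones(len(merged))])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = np.corrcoef(design, rowvar=False)
        bad = [(cats[i], cats[j]) for i in range(len(cats)) for j in range(i + 1, len(cats))
               if abs(cc[i, j]) > 1 - 1e-10]
        raise ValueError(f"rank-deficient design; collinear category pairs: {bad}")

    w = 1.0 / np.maximum(1.0, ell[:, base_ix])
    Xw = design * w[:, None]
    A = design.T @ Xw
    b = Xw.T @ chi2
    theta = np.linalg.solve(A, b)

    a_mat = sub_annot.matrix.astype(float)
    overlap = a_mat.T @ a_mat                       # C x C category overlap counts
    m_c = a_mat.sum(axis=0)
    M = len(merged)

    def functionals(th: np.ndarray) -> np.ndarray:
        tau = th[: len(cats)]
        h2 = overlap @ tau
        h2_tot = h2[base_ix]
        with np.errstate(divide="ignore", invalid="ignore"):
            prop = np.where(h2_tot != 0, h2 / h2_tot, np.nan)
            enr = prop / (m_c / M)
        icpt = th[-1] if fit_intercept else 0.0
        return np.concatenate([tau, h2, prop, enr, [h2_tot, icpt]])

    blocks = np.array_split(np.arange(len(merged)), n_blocks)
    jack = np.empty((n_blocks, 4 * len(cats) + 2))
    for i, blk in enumerate(blocks):
        Ab = design[blk].T @ Xw[blk]
        bb = Xw[blk].T @ chi2[blk]
        jack[i] = functionals(np.linalg.solve(A - Ab, b - bb))
    ses = _jackknife_se(jack)

    full = functionals(theta)
    k = len(cats)
    tau, tau_se = full[:k], ses[:k]
    h2 = full[k:2 * k]
    prop, prop_se = full[2 * k:3 * k], ses[2 * k:3 * k]
    enr, enr_se = full[3 * k:4 * k], ses[3 * k:4 * k]
    h2_tot, h2_tot_se = full[4 * k], ses[4 * k]
    icpt, icpt_se = (theta[-1], ses[4 * k + 1]) if fit_intercept else (0.0, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = tau / tau_se
    p = stats.norm.sf(z)

    table = pd.DataFrame(
        {
            "tau": tau, "tau_se": tau_se, "z": z, "p": p,
            "h2": h2, "prop_h2": prop, "prop_h2_se": prop_se,
            "prop_snps": m_c / M,
            "enrichment": enr, "enrichment_se": enr_se,
        },
        index=pd.Index(cats, name="category"),
    )
    return HeritabilityResult(table=table, intercept=float(icpt),
                              intercept_se=float(icpt_se), h2_total=float(h2_tot),
                              h2_total_se=float(h2_tot_se), n_snps=M,
                              n_blocks=n_blocks)


def celltype_test(sumstats: pd.DataFrame, annot: AnnotationMatrix, panel,
                  ld_window_bp: int | None = None, adjusted: bool = True,
                  n_blocks: int = 200, fit_intercept: bool = True,
                  ldscores: PartitionedLDScores | None = None) -> pd.DataFrame:
    """One stratified fit per cell type: base category plus that cell
    type's annotation, one-sided p on the cell-type coefficient, BH-FDR
    across cell types.

    ``annot`` holds the base plus one column per cell type. LD scores are
    computed once for all categories (or passed in precomputed).
    """
    if ldscores is None:
        ldscores = compute_ld_scores(panel, annot, ld_window_bp=ld_window_bp,
                                     adjusted=adjusted)
    rows = []
    for cat in annot.categories:
        if cat == "base":
            continue
        m_c = int(annot.m_c[cat])
        if m_c == 0:
            rows.append({"cell_type": cat, "M_C": 0, "tested": False,
                         "tau": np.nan, "tau_se": np.nan, "z": np.nan, "p": np.nan,
                         "enrichment": np.nan, "enrichment_se": np.nan,
                         "prop_h2": np.nan, "prop_snps": 0.0})
            continue
        sub_a = annot.subset_categories(["base", cat])
        sub_l = PartitionedLDScores(
            table=ldscores.table[["SNP", "CHR", "BP", "base", cat]],
            categories=["base", cat], adjusted=ldscores.adjusted)
        res = stratified_ldsc(sumstats, sub_l, sub_a, n_blocks=n_blocks,
                              fit_intercept=fit_intercept)
        r = res.table.loc[cat]
        rows.append({"cell_type": cat, "M_C": m_c, "tested": True,
                     "tau": r["tau"], "tau_se": r["tau_se"], "z": r["z"], "p": r["p"],
                     "enrichment": r["enrichment"], "enrichment_se": r["enrichment_se"],
                     "prop_h2": r["prop_h2"], "prop_snps": r["prop_snps"]})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    tested = out["tested"] & out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = fdr_adjust(out.loc[tested, "p"].to_numpy())
    return out


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# matched vs unmatched variance comparison
# ---------------------------------------------------------------------------


@dataclass
class VarianceComparison:
    """Variance-ratio and Levene/Brown-Forsythe comparison of two samples
    of enrichment z-scores (H1: the matched sample has lower variance)."""

    var_matched: float
    var_unmatched: float
    f_stat: float
    f_p: float
    levene_stat: float
    levene_p: float
    n_matched: int
    n_unmatched: int
    degenerate: bool = False


def compare_matched_variance(z_matched, z_unmatched,
                             levene_center: str = "median") -> VarianceComparison:
    """F = s2_unmatched / s2_matched with one-sided p (matched variance
    lower), plus the Levene/Brown-Forsythe test on absolute deviations
    from the chosen center."""
    zm = np.asarray(z_matched, float)
    zu = np.asarray(z_unmatched, float)
    if len(zm) < 3 or len(zu) < 3:
        raise ValueError("each sample needs at least 3 observations")
    s2m = zm.var(ddof=1)
    s2u = zu.var(ddof=1)
    if s2m == 0 and s2u == 0:
        return VarianceComparison(0.0, 0.0, 1.0, 1.0, 0.0, 1.0,
                                  len(zm), len(zu), degenerate=True)
    f = s2u / s2m if s2m > 0 else np.inf
    f_p = float(stats.f.sf(f, len(zu) - 1, len(zm) - 1))
    lev_stat, lev_p = stats.levene(zm, zu, center=levene_center)
    return VarianceComparison(float(s2m), float(s2u), float(f), f_p,
                              float(lev_stat), float(lev_p), len(zm), len(zu))
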