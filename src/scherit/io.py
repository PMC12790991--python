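"""Readers and writers for the plain-text formats used across the
pipeline: MatrixMarket counts with gene/barcode sidecars, cell metadata
TSV, dosage-panel TSV, LDSC-dialect summary statistics, BED gene
coordinates, annotation/LD-score tables, gene-set lists."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import anndata as ad
import scipy.io
import scipy.sparse

from .simulate import GenotypePanel
from .herit import AnnotationMatrix, PartitionedLDScores


# ----- single-cell counts ---------------------------------------------------


def write_counts_mtx(adata: ad.AnnData, outdir: str) -> None:
    """10x-style trio: matrix.mtx (genes x cells), genes.tsv, barcodes.tsv,
    plus cells.tsv with the obs metadata."""
    os.makedirs(outdir, exist_ok=True)
    X = adata.X
    mat = scipy.sparse.csr_matrix(np.asarray(X)).T  # genes x cells on disk
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat, field="integer")
    adata.var.reset_index().to_csv(os.path.join(outdir, "genes.tsv"),
                                   sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False)
    adata.obs.reset_index().to_csv(os.path.join(outdir, "cells.tsv"),
                                   sep="\t", index=False)


def read_counts_mtx(outdir: str) -> ad.AnnData:
    mat = scipy.io.mmread(os.path.join(outdir, "matrix.mtx")).tocsr().T
    genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t")
    cells = pd.read_csv(os.path.join(outdir, "cells.tsv"), sep="\t")
    var = genes.set_index(genes.columns[0])
    obs = cells.set_index(cells.columns[0])
    return ad.AnnData(X=np.asarray(mat.todense()).astype(np.int32), obs=obs, var=var)


# ----- genotype panel -------------------------------------------------------


def write_panel_tsv(panel: GenotypePanel, path: str) -> None:
    """Dosage TSV: SNP, CHR, POS, A1, A2 then one column per individual."""
    dosage_cols = pd.DataFrame(
        panel.dosages.T, columns=[f"I{i + 1}" for i in range(panel.n_individuals)])
    out = pd.concat([panel.variants.reset_index(drop=True), dosage_cols], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    meta = ["SNP", "CHR", "POS", "A1", "A2"]
    ind_cols = [c for c in df.columns if c not in meta]
    dosages = df[ind_cols].to_numpy(np.int8).T
    variants = df[meta].copy()
    variants["CHR"] = variants["CHR"].astype(str)
    return GenotypePanel(dosages=dosages, variants=variants)


# ----- summary statistics ---------------------------------------------------


def write_sumstats(sumstats: pd.DataFrame, path: str) -> None:
    sumstats[["SNP", "A1", "A2", "N", "Z"]].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"SNP", "A1", "A2", "N", "Z"}
    if not required.issubset(df.columns):
        raise ValueError(f"sumstats file must have header columns {sorted(required)}")
    if (df["N"] <= 0).any() or not np.isfinite(df["Z"]).all():
        raise ValueError("sumstats require N > 0 and finite Z")
    return df


def check_alleles(sumstats: pd.DataFrame, variants: pd.DataFrame) -> float:
    """Fraction of shared SNPs whose (A1, A2) pair disagrees with the
    variant table (no flipping is performed: chi-square is sign-free)."""
    merged = sumstats.merge(variants, on="SNP", suffixes=("", "_v"))
    if len(merged) == 0:
        return 0.0
    ok = ((merged["A1"] == merged["A1_v"]) & (merged["A2"] == merged["A2_v"])) | \
         ((merged["A1"] == merged["A2_v"]) & (merged["A2"] == merged["A1_v"]))
    return float(1.0 - ok.mean())


# ----- annotations, LD scores, gene sets ------------------------------------


def write_annot(annot: AnnotationMatrix, path: str) -> None:
    """`.annot`-dialect TSV: CHR, BP, SNP then one 0/1 column per category."""
    out = annot.snps[["CHR", "BP", "SNP"]].copy()
    for i, c in enumerate(annot.categories):
        out[c] = annot.matrix[:, i]
    out.to_csv(path, sep="\t", index=False)


def read_annot(path: str) -> AnnotationMatrix:
    df = pd.read_csv(path, sep="\t")
    cats = [c for c in df.columns if c not in ("CHR", "BP", "SNP")]
    return AnnotationMatrix(
        snps=df[["SNP", "CHR", "BP"]].astype({"CHR": str}).reset_index(drop=True),
        matrix=df[cats].to_numpy(np.int8), categories=cats)


def write_ldscore(ldscores: PartitionedLDScores, path: str) -> None:
    """`.l2.ldscore`-dialect TSV: CHR, SNP, BP then one l column per category."""
    cols = ["CHR", "SNP", "BP"] + list(ldscores.categories)
    ldscores.table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_gene_set(genes, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(g) for g in genes) + "\n")


def read_gene_set(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
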