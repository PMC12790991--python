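"""Expression-derived copy-number profiles.

Somatic copy-number alterations leave a footprint in expression: genes in
an amplified region are, on average, expressed above a diploid reference.
The profile here centers each gene on its mean over a reference cell
population, clips extremes, orders genes by genomic position, smooths
along each chromosome with a centered moving average over gene order
(the window shrinks symmetrically at chromosome edges and never spans
chromosomes), and finally subtracts each cell's median smoothed value.
The centromere of each chromosome is marked at the last retained gene
before the centromere position (or, when no retained gene precedes it,
the first retained gene after it as a proxy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad

from .cellstate import _expr_frame


@dataclass
class CnvMatrix:
    """Smoothed relative-expression profile: cells x genes (genomic
    order), the ordered gene coordinates, and per-chromosome centromere
    marks (gene id, or absent)."""

    values: pd.DataFrame
    gene_info: pd.DataFrame
    centromeres: dict[str, str]


def _chrom_sort_key(c: str):
    c = str(c).removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def moving_average(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis; at position j the
    halfwidth shrinks to min((window - 1) // 2, j, n - 1 - j)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    X = np.asarray(X, float)
    g = X.shape[-1]
    h = (window - 1) // 2
    if h == 0 or g == 1:
        return X.copy()
    cs = np.concatenate([np.zeros(X.shape[:-1] + (1,)), np.cumsum(X, axis=-1)], axis=-1)
    j = np.arange(g)
    hh = np.minimum(h, np.minimum(j, g - 1 - j))
    lo, hi = j - hh, j + hh
    return (cs[..., hi + 1] - cs[..., lo]) / (hi - lo + 1)


def infer_cnv_profile(expr, coords: pd.DataFrame, reference_cells,
                      window: int = 150, min_mean_expr: float = 0.1,
                      clip: float = 3.0,
                      centromere_positions: dict[str, int] | None = None) -> CnvMatrix:
    """Smoothed relative SCNA profile of every cell against a reference.

    ``expr`` is log-normalized expression (cells x genes); ``coords`` has
    columns gene/chrom/start/end (1-based inclusive). Pipeline: drop
    genes with overall mean expression below ``min_mean_expr``; center
    each gene on its reference-cell mean; clip to ``+/- clip``; order by
    (chromosome, start); smooth per chromosome with
    :func:`moving_average`; subtract each cell's median smoothed value.
    """
    df = _expr_frame(expr)
    ref = [c for c in reference_cells if c in df.index]
    if not ref:
        raise ValueError("reference cell set is empty or disjoint from the matrix")
    overlap = set(ref) & (set(df.index) - set(ref))
    if len(ref) < len(list(reference_cells)):
        warnings.warn(f"{len(list(reference_cells)) - len(ref)} reference cell(s) "
                      "absent from the expression matrix")

    keep = df.columns[df.mean(axis=0) >= min_mean_expr]
    df = df[keep]
    if df.shape[1] == 0:
        raise ValueError("no gene passes the min_mean_expr filter")

    cix = coords.drop_duplicates("gene").set_index("gene")
    have = [g for g in df.columns if g in cix.index]
    n_missing = df.shape[1] - len(have)
    if n_missing:
        warnings.warn(f"{n_missing} retained gene(s) without coordinates dropped")
    if len(have) < 0.9 * df.shape[1]:
        raise ValueError("gene coordinates cover fewer than 90% of retained genes")
    df = df[have]

    centered = df - df.loc[ref].mean(axis=0)
    centered = centered.clip(-clip, clip)

    info = cix.loc[have, ["chrom", "start", "end"]].reset_index()
    info["_key"] = info["chrom"].map(_chrom_sort_key)
    info = info.sort_values(["_key", "start"], kind="stable").drop(columns="_key")
    info = info.reset_index(drop=True)
    centered = centered[info["gene"]]

    smoothed = np.empty_like(centered.to_numpy(float))
    for chrom, grp in info.groupby("chrom", sort=False):
        ix = grp.index.to_numpy()
        block = centered.iloc[:, ix].to_numpy(float)
        if len(ix) < 2:
            warnings.warn(f"chromosome {chrom!r} has fewer than 2 retained genes; "
                          "passed through unsmoothed")
            smoothed[:, ix] = block
        else:
            smoothed[:, ix] = moving_average(block, window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)

    values = pd.DataFrame(smoothed, index=centered.index, columns=centered.columns)
    cen = (mark_centromeres(info, centromere_positions)
           if centromere_positions is not None else {})
    return CnvMatrix(values=values, gene_info=info, centromeres=cen)


def mark_centromeres(gene_info: pd.DataFrame,
                     centromere_positions: dict[str, int]) -> dict[str, str]:
    """Per chromosome, the last retained gene starting before the
    centromere position; when every retained gene lies after it, the
    first gene of the chromosome serves as a proxy mark. Chromosomes
    absent from the position table get no mark (with a warning)."""
    marks: dict[str, str] = {}
    for chrom, grp in gene_info.groupby("chrom", sort=False):
        if chrom not in centromere_positions:
            warnings.warn(f"no centromere position for chromosome {chrom!r}; no mark")
            continue
        cen = centromere_positions[chrom]
        grp = grp.sort_values("start", kind="stable")
        before = grp[grp["start"] < cen]
        marks[str(chrom)] = str((before.iloc[-1] if len(before) else grp.iloc[0])["gene"])
    return marks


def read_bed(path) -> pd.DataFrame:
    """Gene coordinates from BED (0-based half-open) converted to 1-based
    inclusive. Columns used: chrom, start, end, name, [score, strand]."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    coords = pd.DataFrame({
        "gene": bed[3].astype(str),
        "chrom": bed[0].astype(str),
        "start": bed[1].astype(int) + 1,
        "end": bed[2].astype(int),
        "strand": bed[5].astype(str) if bed.shape[1] > 5 else "+",
    })
    return coords.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
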