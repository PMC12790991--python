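"""Single-cell processing statistics.

Staged QC filtering (min detected genes, MAD outlier trim, mitochondrial
cuts), log-normalization, cluster marker statistics (log fold change and
the pct.ratio cluster-specificity measure), the smoothed-difference PC
retention rule, per-gene cell-type specificity, and top-fraction gene-set
construction.

Expression containers are :class:`anndata.AnnData` (cells x genes);
cluster labels come from ``obs`` or an aligned Series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad


def _labels_of(adata: ad.AnnData, labels) -> pd.Series | None:
    if labels is None:
        if "cell_type" in adata.obs:
            return adata.obs["cell_type"].astype(str)
        return None
    if isinstance(labels, str):
        return adata.obs[labels].astype(str)
    s = pd.Series(labels)
    if len(s) != adata.n_obs:
        raise ValueError("labels length does not match number of cells")
    s.index = adata.obs_names
    return s.astype(str)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QcThresholds:
    """Staged QC parameters: minimum detected genes, the MAD multiplier
    for total-count/detected-gene outliers, the initial mitochondrial
    fraction cap, and the per-cell-type top-fraction mitochondrial cut.
    ``min_genes`` defaults to 1000 (lowered to 500 for cohorts where a
    wider spectrum of cells should be kept)."""

    min_genes: int = 1000
    mad_k: float = 3.0
    mito_init: float = 0.30
    mito_top_frac: float = 0.15

    def validate(self) -> None:
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")
        if not 0 < self.mito_init <= 1:
            raise ValueError("mito_init must be in (0, 1]")
        if not 0 <= self.mito_top_frac < 1:
            raise ValueError("mito_top_frac must be in [0, 1)")


@dataclass
class QcReport:
    n_input: int
    removed_min_genes: int
    removed_mad: int
    removed_mito_init: int
    removed_mito_top: int
    n_retained: int
    mito_top_applied: bool
    labels_available: bool

    @property
    def total_removed(self) -> int:
        return (self.removed_min_genes + self.removed_mad +
                self.removed_mito_init + self.removed_mito_top)


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation (no 1.4826 consistency factor)."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def qc_filter(adata: ad.AnnData, thr: QcThresholds | None = None, labels=None,
              apply_mito_top: bool = True) -> tuple[ad.AnnData, QcReport]:
    """Staged cell filter.

    1. drop cells with fewer than ``min_genes`` detected genes;
    2. drop cells outside median +/- mad_k * MAD (both tails) on total
       counts and on detected genes, MAD unscaled, deviation exactly at
       the bound kept;
    3. drop cells with mitochondrial fraction above ``mito_init``;
    4. within each cell type, drop the top ``mito_top_frac`` of the
       surviving cells by mitochondrial fraction (skipped when no labels
       are available or ``apply_mito_top`` is false, e.g. on re-runs).

    Raises if any stage empties the matrix.
    """
    thr = thr or QcThresholds()
    thr.validate()
    lab = _labels_of(adata, labels)
    X = _dense(adata.X)
    detected = (X > 0).sum(axis=1)
    total = X.sum(axis=1).astype(float)
    if "is_mito" in adata.var:
        mito = X[:, adata.var["is_mito"].to_numpy(bool)].sum(axis=1)
    else:
        mito = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / total, 0.0)

    keep = np.ones(adata.n_obs, dtype=bool)

    s1 = keep & (detected >= thr.min_genes)
    removed1 = int(keep.sum() - s1.sum())
    if not s1.any():
        raise ValueError("QC stage 1 (min detected genes) removed every cell")

    s2 = s1.copy()
    for metric in (total, detected):
        vals = metric[s2]
        med, mad = np.median(vals), _mad(vals)
        ok = np.abs(metric - med) <= thr.mad_k * mad
        s2 &= ok
    removed2 = int(s1.sum() - s2.sum())
    if not s2.any():
        raise ValueError("QC stage 2 (MAD outlier trim) removed every cell")

    s3 = s2 & (mito_frac <= thr.mito_init)
    removed3 = int(s2.sum() - s3.sum())
    if not s3.any():
        raise ValueError("QC stage 3 (initial mitochondrial cut) removed every cell")

    removed4 = 0
    s4 = s3.copy()
    did_stage4 = apply_mito_top and lab is not None
    if did_stage4:
        lab_arr = lab.to_numpy()
        for ct in np.unique(lab_arr[s3]):
            ix = np.flatnonzero(s3 & (lab_arr == ct))
            n_drop = int(math.floor(thr.mito_top_frac * len(ix)))
            if n_drop:
                order = ix[np.argsort(-mito_frac[ix], kind="stable")]
                s4[order[:n_drop]] = False
                removed4 += n_drop
        if not s4.any():
            raise ValueError(
                "QC stage 4 (per-cell-type mitochondrial cut) removed every cell")

    report = QcReport(
        n_input=adata.n_obs, removed_min_genes=removed1, removed_mad=removed2,
        removed_mito_init=removed3, removed_mito_top=removed4,
        n_retained=int(s4.sum()), mito_top_applied=did_stage4,
        labels_available=lab is not None,
    )
    return adata[s4].copy(), report


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size log-normalization: x = ln(1 + scale * count / total).

    Returns a copy with normalized ``X`` and the raw counts preserved in
    ``layers['counts']``. A cell with zero total counts is an error.
    """
    X = _dense(adata.X).astype(float)
    total = X.sum(axis=1)
    if (total <= 0).any():
        bad = adata.obs_names[total <= 0].tolist()[:5]
        raise ValueError(f"cells with zero total counts (should not survive QC): {bad}")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(scale * X / total[:, None])
    return out


# ---------------------------------------------------------------------------
# marker statistics
# ---------------------------------------------------------------------------


def compute_marker_stats(adata: ad.AnnData, labels=None, min_pct: float = 0.30,
                         min_logfc: float = 0.1) -> pd.DataFrame:
    """Per-(cluster, gene) marker statistics on log-normalized expression.

    ``log_fc`` is the natural log of the ratio of in-cluster vs rest mean
    de-logged expression (mean expm1 + 1 on each side); ``pct_in`` /
    ``pct_out`` are the fractions of cells with nonzero expression;
    ``pct_ratio = pct_in / pct_out`` with +inf when a gene is entirely
    cluster-exclusive (so exclusive genes outrank all finite ratios).
    ``passes`` marks genes with pct_in >= min_pct and log_fc >= min_logfc;
    rows are ordered per cluster by (passes, log_fc, pct_ratio) descending.
    Clusters with fewer than 3 cells are excluded with a warning.
    """
    lab = _labels_of(adata, labels)
    if lab is None:
        raise ValueError("cluster labels are required")
    clusters = [c for c in pd.unique(lab)]
    if len(clusters) < 2:
        raise ValueError("marker statistics need at least 2 clusters")
    X = _dense(adata.X).astype(float)
    expm1 = np.expm1(X)
    nonzero = X > 0
    genes = adata.var_names.to_numpy()

    frames = []
    for cl in clusters:
        in_mask = (lab == cl).to_numpy()
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {cl!r} has fewer than 3 cells; excluded")
            continue
        out_mask = ~in_mask
        mean_in = expm1[in_mask].mean(axis=0)
        mean_out = expm1[out_mask].mean(axis=0)
        log_fc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        pct_in = nonzero[in_mask].mean(axis=0)
        pct_out = nonzero[out_mask].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_ratio = np.where(pct_out > 0, pct_in / pct_out,
                                 np.where(pct_in > 0, np.inf, 0.0))
        df = pd.DataFrame({
            "cluster": cl, "gene": genes, "log_fc": log_fc,
            "pct_in": pct_in, "pct_out": pct_out, "pct_ratio": pct_ratio,
        })
        df["passes"] = (df["pct_in"] >= min_pct) & (df["log_fc"] >= min_logfc)
        df = df.sort_values(["passes", "log_fc", "pct_ratio"],
                            ascending=False, kind="stable")
        frames.append(df)
    if not frames:
        raise ValueError("no cluster with at least 3 cells")
    return pd.concat(frames, ignore_index=True)


def top_markers(stats: pd.DataFrame, cluster: str, n: int | None = None) -> pd.DataFrame:
    """Passing marker rows of one cluster, in rank order."""
    sub = stats[(stats["cluster"] == cluster) & stats["passes"]]
    return sub.head(n) if n is not None else sub


# ---------------------------------------------------------------------------
# PC retention
# ---------------------------------------------------------------------------


def select_pcs(explained_variance, threshold: float = 0.02,
               halfwidth: int = 2) -> int:
    """Number of principal components to retain.

    ``explained_variance`` is the non-increasing percent-of-variance
    sequence. The rule: take consecutive differences, smooth them with a
    centered rolling mean of ``2 * halfwidth + 1`` points (window shrinks
    at the edges), and return the first index whose smoothed difference
    falls below ``threshold``; if none does, retain all components.
    """
    v = np.asarray(explained_variance, float)
    if v.size < 2:
        raise ValueError("need at least 2 components")
    if np.any(np.diff(v) > 1e-9):
        raise ValueError("explained variance must be non-increasing")
    d = v[:-1] - v[1:]
    smoothed = np.array([
        d[max(0, i - halfwidth): i + halfwidth + 1].mean() for i in range(d.size)
    ])
    below = np.flatnonzero(smoothed < threshold)
    return int(below[0] + 1) if below.size else int(v.size)


# ---------------------------------------------------------------------------
# specificity and gene sets
# ---------------------------------------------------------------------------


def compute_specificity(adata: ad.AnnData, labels=None,
                        aggregation: str = "mean-lognorm") -> pd.DataFrame:
    """Per-gene expression share across cell types.

    Each gene's per-type expression (default: mean log-normalized, see
    ``aggregation``: ``mean-lognorm`` | ``mean-counts`` | ``summed-counts``)
    is divided by its total over all types, so rows sum to 1. Genes with
    zero expression in every type are dropped.
    """
    lab = _labels_of(adata, labels)
    if lab is None:
        raise ValueError("cell-type labels are required")
    if aggregation == "mean-lognorm":
        X = _dense(adata.X).astype(float)
    elif aggregation in ("mean-counts", "summed-counts"):
        if "counts" in adata.layers:
            X = _dense(adata.layers["counts"]).astype(float)
        else:
            X = _dense(adata.X).astype(float)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    df = pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names)
    grouped = df.groupby(lab.to_numpy())
    per_type = grouped.sum().T if aggregation == "summed-counts" else grouped.mean().T
    total = per_type.sum(axis=1)
    per_type = per_type.loc[total > 0]
    spec = per_type.div(per_type.sum(axis=1), axis=0)
    spec.index.name = "gene"
    return spec


def top_specific_genes(spec: pd.DataFrame, fraction: float = 0.15,
                       keep_ties: bool = False) -> dict[str, list[str]]:
    """Per cell type, the ``ceil(fraction * n_genes)`` genes with highest
    specificity; ties at the cutoff broken lexicographically by gene id
    (or all kept with ``keep_ties``)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = math.ceil(fraction * len(spec))
    sets: dict[str, list[str]] = {}
    for ct in spec.columns:
        ranked = spec[ct].sort_index().sort_values(ascending=False, kind="stable")
        if keep_ties and n < len(ranked):
            cutoff = ranked.iloc[n - 1]
            sets[ct] = ranked[ranked >= cutoff].index.tolist()
        else:
            sets[ct] = ranked.index[:n].tolist()
    return sets
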