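"""Gene-set module scores, cell-cycle phase assignment, and the
cluster-level relative proliferation index.

The module score is the binned signature-minus-control statistic: genes
are binned by average expression, each signature gene contributes a
seeded draw of control genes from its own bin, and a cell's score is the
mean expression of the signature minus the mean of the control pool.
A cell is called G1 when both S and G2/M scores fall at or below the
phase threshold, otherwise the larger score wins (ties go to S). The
relative proliferation index of a cluster is (#S + #G2M) / #G1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad

from .sc import _dense, _labels_of


def _expr_frame(expr) -> pd.DataFrame:
    if isinstance(expr, ad.AnnData):
        return pd.DataFrame(_dense(expr.X), index=expr.obs_names,
                            columns=expr.var_names)
    return pd.DataFrame(expr)


def module_score(expr, gene_set, n_bins: int = 25, n_ctrl: int = 100,
                 seed: int = 0, method: str = "binned-control") -> pd.Series:
    """Per-cell signature score.

    ``binned-control`` (default): bin all genes into ``n_bins`` equal-size
    bins by average expression; for each signature gene draw ``n_ctrl``
    control genes from its bin with replacement (seeded); score =
    mean(signature) - mean(control pool). ``correlation``: Pearson
    correlation of each cell's profile with the binary signature vector.
    """
    df = _expr_frame(expr)
    genes = [g for g in gene_set if g in df.columns]
    missing = [g for g in gene_set if g not in df.columns]
    if not genes:
        raise ValueError(f"no signature gene present in the expression matrix; "
                         f"missing: {missing[:10]}")
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) absent; using {len(genes)}")

    if method == "correlation":
        sig = df.columns.isin(genes).astype(float)
        X = df.to_numpy(float)
        Xc = X - X.mean(axis=1, keepdims=True)
        sc = sig - sig.mean()
        denom = np.sqrt((Xc ** 2).sum(axis=1) * (sc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(denom > 0, (Xc @ sc) / denom, 0.0)
        return pd.Series(score, index=df.index, name="score")
    if method != "binned-control":
        raise ValueError(f"unknown method {method!r}")

    n_bins = min(n_bins, df.shape[1])
    avg = df.mean(axis=0)
    # equal-size bins by rank of average expression
    bins = pd.qcut(avg.rank(method="first"), n_bins, labels=False)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    ctrl: list[str] = []
    for g in genes:
        pool = bins.index[bins == bins[g]]
        ctrl.extend(rng.choice(pool, size=n_ctrl, replace=True))
    score = df[genes].mean(axis=1) - df[ctrl].mean(axis=1)
    score.name = "score"
    return score


def assign_cell_cycle(expr, s_genes, g2m_genes, phase_threshold: float = 0.0,
                      seed: int = 0, **score_kwargs) -> pd.DataFrame:
    """Per-cell S and G2/M module scores and the assigned phase.

    G1 when both scores are at or below ``phase_threshold``; otherwise the
    phase of the larger score, with exact ties (both above threshold)
    resolved deterministically to S.
    """
    s = module_score(expr, s_genes, seed=seed, **score_kwargs)
    g2m = module_score(expr, g2m_genes, seed=seed + 1, **score_kwargs)
    phase = np.where(
        (s <= phase_threshold) & (g2m <= phase_threshold), "G1",
        np.where(s >= g2m, "S", "G2M"))
    return pd.DataFrame({"S": s, "G2M": g2m, "phase": phase}, index=s.index)


def relative_proliferation_index(phases: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster (#S + #G2M) / #G1 with the raw phase counts.

    A cluster without G1 cells gets index +inf and ``g1_empty = True``.
    """
    lab = pd.Series(labels)
    if len(lab) != len(phases):
        raise ValueError("labels length does not match phases")
    lab.index = phases.index
    rows = []
    for cl, grp in phases.groupby(lab.to_numpy()):
        counts = grp["phase"].value_counts()
        g1 = int(counts.get("G1", 0))
        s = int(counts.get("S", 0))
        g2m = int(counts.get("G2M", 0))
        if g1 == 0:
            warnings.warn(f"cluster {cl!r} has no G1 cell; index reported as +inf")
            idx = np.inf
        else:
            idx = (s + g2m) / g1
        rows.append({"cluster": cl, "n_g1": g1, "n_s": s, "n_g2m": g2m,
                     "index": idx, "g1_empty": g1 == 0})
    return pd.DataFrame(rows).set_index("cluster")
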