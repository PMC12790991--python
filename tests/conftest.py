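import numpy as np
import pandas as pd
import pytest

from scherit import (ScSimConfig, LdSimConfig, simulate_sc_counts,
                     simulate_ld_reference)


@pytest.fixture(scope="session")
def sc_small():
    """Small planted-marker dataset: 4 types x 60 cells, 400 genes."""
    cfg = ScSimConfig(n_cell_types=4, cells_per_type=60, n_genes=400,
                      n_markers_per_type=20, marker_fold=8.0, n_mito_genes=10,
                      seed=7)
    adata, markers = simulate_sc_counts(cfg)
    return adata, markers, cfg


@pytest.fixture(scope="session")
def panel_small():
    """Compact LD panel: 6 blocks x 10 SNPs, 300 individuals."""
    cfg = LdSimConfig(n_individuals=300, n_blocks=6, block_size=10,
                      within_block_corr=0.8, seed=11)
    return simulate_ld_reference(cfg)


def brute_force_ld_scores(dosages, annot_matrix, chrom, bp, ld_window_bp=None,
                          adjusted=False):
    """Independent double-loop partitioned LD score oracle."""
    n, M = dosages.shape
    X = dosages.astype(float)
    ell = np.zeros((M, annot_matrix.shape[1]))
    for j in range(M):
        for k in range(M):
            if chrom[j] != chrom[k]:
                continue
            if ld_window_bp is not None and abs(bp[j] - bp[k]) > ld_window_bp:
                continue
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            r2 = r * r
            if adjusted:
                r2 = r2 - (1 - r2) / (n - 2)
            for c in range(annot_matrix.shape[1]):
                if annot_matrix[k, c]:
                    ell[j, c] += r2
    return ell


def brute_force_moving_average(X, window):
    """Independent loop implementation of the shrinking centered mean."""
    X = np.asarray(X, float)
    out = np.empty_like(X)
    g = X.shape[1]
    h = (window - 1) // 2
    for j in range(g):
        hh = min(h, j, g - 1 - j)
        out[:, j] = X[:, j - hh: j + hh + 1].mean(axis=1)
    return out


def brute_force_bh(p):
    """Step-up Benjamini-Hochberg, written independently."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, m * p[idx] / rank)
        q[idx] = val
        prev = val
    return np.minimum(q, 1.0)
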