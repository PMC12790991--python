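"""Generate the synthetic study data: clustered single-cell counts with
planted markers, an LD-structured genotype reference panel, and GWAS
summary statistics enriched fivefold in one annotation category.

Writes the 10x-style count trio, the dosage panel, the sumstats table and
the ground-truth sidecars under scratch/data/ (matrices are bulky; the
downstream drivers regenerate everything from the seed instead of
reading these files).
"""

import json
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from scherit import (ScSimConfig, LdSimConfig, GwasSimConfig,
                     simulate_sc_counts, simulate_ld_reference, simulate_gwas,
                     make_block_annotation)
from scherit import io as sio

SEED = 20250930
OUT = os.path.join(os.path.dirname(__file__), "..", "scratch", "data")


def main():
    os.makedirs(OUT, exist_ok=True)

    sc_cfg = ScSimConfig(seed=SEED)
    adata, markers = simulate_sc_counts(sc_cfg)
    sio.write_counts_mtx(adata, OUT)
    with open(os.path.join(OUT, "marker_truth.json"), "w") as fh:
        json.dump(markers, fh, indent=1)
    print(f"single-cell counts: {adata.n_obs} cells x {adata.n_vars} genes, "
          f"{sc_cfg.n_cell_types} cell types, fold-{sc_cfg.marker_fold} markers")

    ld_cfg = LdSimConfig(n_individuals=500, n_blocks=200, block_size=10, seed=SEED)
    panel = simulate_ld_reference(ld_cfg)
    sio.write_panel_tsv(panel, os.path.join(OUT, "panel.tsv"))
    print(f"reference panel: {panel.n_individuals} individuals x "
          f"{panel.n_snps} SNPs in {ld_cfg.n_blocks} LD blocks")

    annot = make_block_annotation(panel, 0.1, name="CT", seed=SEED)
    sio.write_annot(annot, os.path.join(OUT, "truth.annot"))
    gw_cfg = GwasSimConfig(h2_total=0.4, enriched_category="CT",
                           true_enrichment=5.0, gwas_n=5000, seed=SEED)
    ss = simulate_gwas(panel, annot, gw_cfg)
    sio.write_sumstats(ss, os.path.join(OUT, "trait.sumstats"))
    chi2 = float((ss["Z"] ** 2).mean())
    print(f"GWAS: N={gw_cfg.gwas_n}, h2={gw_cfg.h2_total}, planted fold "
          f"{gw_cfg.true_enrichment} in {int(annot.m_c['CT'])} SNPs; "
          f"mean chi2 = {chi2:.2f}")


if __name__ == "__main__":
    main()
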