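"""The core analysis: from cell-type gene sets to per-cell-type GWAS
enrichment by stratified LD score regression.

Runs the full chain on the scaled synthetic genome — specificity gene
sets from planted-marker expression, 2 kb gene windows to SNP
annotations, partitioned LD scores from the reference panel, one
stratified fit per cell type with block-jackknife SEs and BH-FDR — for a
GWAS enriched fivefold in the first cell type's annotation, then the
calibration companions: planted-enrichment recovery over 20 GWAS
replicates and the matched/unmatched variance comparison. Writes the
results tables under results/.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from scherit import compare_matched_variance
from scherit.experiments import (celltype_ranking_experiment,
                                 enrichment_recovery_experiment,
                                 variance_fixture)

SEED = 20250930
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(OUT, exist_ok=True)

    rank = celltype_ranking_experiment(seed=SEED, n_replicates=10)
    res = rank["results_last"]
    res.to_csv(os.path.join(OUT, "celltype_enrichment.tsv"), sep="\t",
               index=False)
    print(f"planted cell type: {rank['planted']}; smallest p in "
          f"{rank['n_first']}/{rank['n_replicates']} GWAS replicates")
    show = res[["cell_type", "M_C", "enrichment", "enrichment_se", "z", "p", "q"]]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    rec = enrichment_recovery_experiment(seed=SEED, n_replicates=20)
    rec["table"].to_csv(os.path.join(OUT, "enrichment_recovery.tsv"),
                        sep="\t", index=False)
    print(f"\nplanted fold-5 architecture: true enrichment "
          f"{rec['truth']:.3f}; estimate within 2 jackknife SEs in "
          f"{rec['n_covered']}/{rec['n_replicates']} replicates "
          f"(median estimate "
          f"{rec['table']['enrichment'].median():.2f})")

    zm, zu = variance_fixture(seed=SEED, n=30, variance_ratio=4.0)
    cmp = compare_matched_variance(zm, zu)
    pd.DataFrame([cmp.__dict__]).to_csv(
        os.path.join(OUT, "variance_comparison.tsv"), sep="\t", index=False)
    print(f"\nmatched vs unmatched z-score variance (planted ratio 4): "
          f"F = {cmp.f_stat:.2f}, one-sided p = {cmp.f_p:.2g}; "
          f"Levene p = {cmp.levene_p:.2g}")


if __name__ == "__main__":
    main()
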