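"""Cell-cycle phase assignment and the relative proliferation index on a
population with planted phase structure.

One cluster is made highly proliferative (40% S, 20% G2/M), the other
quiescent (5% each); the per-cluster index should separate them sharply.
Writes per-cell phases and the per-cluster index under results/.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from scherit import assign_cell_cycle, relative_proliferation_index
from scherit.experiments import planted_cycle_population

SEED = 20250930
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(OUT, exist_ok=True)
    X, s_genes, g2m_genes, labels, truth = planted_cycle_population(SEED)
    phases = assign_cell_cycle(X, s_genes, g2m_genes, n_bins=1, seed=SEED)
    acc = float((phases["phase"].to_numpy() == truth).mean())
    print(f"phase-call accuracy vs planted truth: {acc:.3f}")
    phases.to_csv(os.path.join(OUT, "cell_phases.tsv"), sep="\t")

    idx = relative_proliferation_index(phases, labels)
    idx.to_csv(os.path.join(OUT, "proliferation_index.tsv"), sep="\t")
    for cl, row in idx.iterrows():
        print(f"{cl}: G1={row.n_g1} S={row.n_s} G2M={row.n_g2m} "
              f"index={row['index']:.2f}")


if __name__ == "__main__":
    main()
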