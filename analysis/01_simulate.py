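"""Generate the default synthetic larval-testis experiment and bulk panel.

Writes the single-cell UMI matrix as a 10x-style MatrixMarket directory,
the truth tables, and the adult-style two-sex bulk panel under results/.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import testisx as tx
from testisx.simulate import write_truth

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 0


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    config = tx.SimConfig(seed=SEED)
    annotation = tx.generate_annotation(config)
    matrix, truth = tx.generate_cells(config, annotation)
    tx.write_counts(matrix, os.path.join(OUT, "sc_counts"))
    annotation.table.to_csv(os.path.join(OUT, "gene_map.tsv"), sep="\t")
    write_truth(truth, os.path.join(OUT, "truth"))

    panel = tx.generate_bulk_panel(config, n_tissues=8, n_reps=4)
    panel.counts.to_frame().T.to_csv(os.path.join(OUT, "bulk_counts.tsv"), sep="\t")
    panel.meta.to_csv(os.path.join(OUT, "bulk_meta.tsv"), sep="\t")

    by_type = truth.cells["cell_type"].value_counts()
    print(f"single-cell matrix: {matrix.shape[0]} cells x {matrix.shape[1]} genes")
    print("cells per type:", dict(by_type))
    print(f"bulk panel: {panel.counts.shape[0]} samples (8 tissues x 2 sexes x 4 reps)")
    print(f"outputs in {os.path.abspath(OUT)} (seed {SEED})")


if __name__ == "__main__":
    main()
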