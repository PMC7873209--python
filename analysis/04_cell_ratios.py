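"""Per-cell chromosome-element ratios and element totals by cell type.

The central readout: X:A and 4th:A gene-count-normalized ratios per cell,
on the all-expressed and CTSP gene sets, summarized per cell type
(median, IQR, notch CI), plus Y and genome-wide normalized totals.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

import testisx as tx

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    config = tx.SimConfig(seed=0)
    annotation = tx.generate_annotation(config)
    matrix, truth = tx.generate_cells(config, annotation)
    norm = tx.normalize(matrix, "cpm")
    labels = truth.cells["cell_type"]

    expressed = set(tx.expressed_genes(matrix, min_cells=3))
    ctsp = tx.compute_ctsp(matrix)
    sets = {
        "all": expressed,
        "ctsp": set(ctsp.index[ctsp["ctsp_member"]]) ,
    }

    summaries = []
    for set_name, genes in sets.items():
        for focal in ("X", "4"):
            if not any(g.startswith(focal + ".") for g in genes):
                continue
            table = tx.chromosome_ratio(norm, annotation, gene_set=genes, focal=focal)
            summary = tx.summarize_by_type(table["ratio"], labels)
            summary.insert(0, "focal", focal)
            summary.insert(0, "gene_set", set_name)
            summaries.append(summary.reset_index())
    ratios = pd.concat(summaries, ignore_index=True)
    ratios.to_csv(os.path.join(OUT, "ratio_summaries.tsv"), sep="\t", index=False)

    y_total = tx.element_expression(norm, annotation, "Y")
    genome = tx.element_expression(norm, annotation, "genome")
    totals = tx.summarize_by_type(y_total, labels).add_prefix("y_")
    totals.to_csv(os.path.join(OUT, "y_expression_by_type.tsv"), sep="\t")

    germ_order = ["G", "E1", "M1", "L1"]
    view = ratios[(ratios["gene_set"] == "all") & (ratios["focal"] == "X")]
    view = view.set_index("cell_type").loc[germ_order + ["C1", "T", "P"], "median"]
    print("median X:A (all expressed genes) along germline then soma:")
    print(view.round(3).to_string())
    print("\nmedian Y totals (cpm) per type:")
    print(totals["y_median"].round(1).to_string())
    print("\nfull summaries in results/ratio_summaries.tsv")


if __name__ == "__main__":
    main()
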