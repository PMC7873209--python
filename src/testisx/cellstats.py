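"""Per-cell measures: chromosome-element ratios, totals, enrichment scores.

The central statistic is the gene-count-normalized element:A expression
ratio computed for every cell:

    R_c = (sum_{g in S and focal} cpm_gc / |S and focal|)
        / (sum_{g in S and A}     cpm_gc / |S and A|)

where S is the active gene set (all expressed genes, or one of the
housekeeping subsets) and A the major autosomal arms. The gene counts are
set sizes, not per-cell detected counts, so the denominator of each mean is
the same for every cell and per-cell sequencing depth cancels exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, MAJOR_AUTOSOMES


def chromosome_ratio(
    norm: CountMatrix,
    annotation: GeneAnnotation,
    gene_set=None,
    focal: str = "X",
    autosomes: frozenset = MAJOR_AUTOSOMES,
) -> pd.DataFrame:
    """Per-cell focal-element : major-autosome expression ratio.

    ``norm`` must be depth-normalized (cpm); ``gene_set`` defaults to all
    annotated genes present in the matrix. Cells with zero autosomal
    expression over the set are marked invalid (ratio NaN).
    """
    element = annotation.element.reindex(norm.var_names)
    in_set = (
        norm.var_names.isin(gene_set)
        if gene_set is not None
        else ~element.isna().to_numpy()
    )
    focal_mask = in_set & (element == focal).to_numpy()
    auto_mask = in_set & element.isin(autosomes).to_numpy()
    n_focal, n_auto = int(focal_mask.sum()), int(auto_mask.sum())
    if n_focal == 0:
        raise ValueError(f"gene set has no genes on focal element {focal!r}")
    if n_auto == 0:
        raise ValueError("gene set has no genes on the autosomal arms")

    csc = norm.X.tocsc()
    focal_sum = np.asarray(csc[:, np.flatnonzero(focal_mask)].sum(axis=1)).ravel()
    auto_sum = np.asarray(csc[:, np.flatnonzero(auto_mask)].sum(axis=1)).ravel()
    valid = auto_sum > 0
    ratio = np.full(norm.shape[0], np.nan)
    ratio[valid] = (focal_sum[valid] / n_focal) / (auto_sum[valid] / n_auto)
    return pd.DataFrame(
        {
            "ratio": ratio,
            "n_focal_genes": n_focal,
            "n_autosome_genes": n_auto,
            "valid": valid,
        },
        index=norm.obs_names,
    )


def element_expression(
    norm: CountMatrix, annotation: GeneAnnotation, element: str = "genome"
) -> pd.Series:
    """Per-cell summed normalized expression of one element (or the genome)."""
    if element == "genome":
        totals = np.asarray(norm.X.sum(axis=1)).ravel()
    else:
        genes = annotation.genes_of(element)
        mask = norm.var_names.isin(genes)
        totals = np.asarray(norm.X.tocsc()[:, np.flatnonzero(mask)].sum(axis=1)).ravel()
    return pd.Series(totals, index=norm.obs_names, name=element)


def gsea_cell_score(
    norm: CountMatrix, gene_set, weight: float = 1.0
) -> pd.Series:
    """Per-cell GSEA enrichment score for one gene set.

    For each cell, genes are ranked by expression (descending, ties broken
    by gene id). Walking down the list, set members add
    |expression|^weight / sum(|expression of members|^weight) and
    non-members subtract 1/(N - |S|); the enrichment score is the running
    sum's maximum deviation from zero, signed. ES in [-1, 1]: +1 when the
    set sits at the very top of every ranking, -1 at the very bottom.
    """
    genes = norm.var_names
    members = np.asarray(genes.isin(gene_set))
    n_in = int(members.sum())
    n = len(genes)
    if n_in == 0 or n_in == n:
        raise ValueError("gene set must be a non-empty proper subset of genes")

    # Sort columns by gene id so a stable sort on -expression breaks ties by id.
    order = np.argsort(genes.to_numpy().astype(str))
    dense = norm.X.toarray()[:, order]
    members_sorted = members[order]

    rank = np.argsort(-dense, axis=1, kind="stable")
    hit = members_sorted[rank]  # cells x genes, in ranked order
    expr = np.take_along_axis(dense, rank, axis=1)

    hit_w = np.where(hit, np.abs(expr) ** weight, 0.0)
    hit_totals = hit_w.sum(axis=1, keepdims=True)
    flat = hit_totals.ravel() == 0  # all member expression zero: unweighted
    if flat.any():
        hit_w[flat] = hit[flat].astype(float)
        hit_totals[flat] = n_in
    running = np.cumsum(hit_w / hit_totals - (~hit) / (n - n_in), axis=1)
    peak = np.argmax(np.abs(running), axis=1)
    es = running[np.arange(len(peak)), peak]
    return pd.Series(es, index=norm.obs_names, name="es")


def summarize_by_type(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Per-type median, IQR, notch 95% CI of the median, and n.

    Quartiles use linear interpolation; the notch interval is
    median +/- 1.57 * IQR / sqrt(n). Only valid (non-NaN) values count.
    Types with no valid cells are reported with NaN summaries and n = 0.
    """
    labels = pd.Series(labels).reindex(values.index)
    rows = {}
    for t, grp in values.groupby(labels.astype(object)):
        vals = grp.dropna().to_numpy()
        if vals.size == 0:
            rows[t] = dict.fromkeys(
                ("median", "iqr", "ci_lo", "ci_hi"), np.nan
            ) | {"n": 0}
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        half = 1.57 * iqr / np.sqrt(vals.size)
        rows[t] = {
            "median": med,
            "iqr": iqr,
            "ci_lo": med - half,
            "ci_hi": med + half,
            "n": int(vals.size),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("cell_type")
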