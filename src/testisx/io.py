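"""Reading, writing and normalizing expression matrices.

Single-cell matrices travel as 10x-style MatrixMarket triplet directories
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``/``genes.tsv``, optionally
gzipped); bulk panels as gene x sample TSV. Normalization is counts-per-million
for 3' UMI data (UMI counts are not length-proportional) and length-corrected
TPM for bulk reads.
"""

from __future__ import annotations

import gzip
import logging
import os
import warnings

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.stats import spearmanr

from .containers import CountMatrix, FormatError, GeneAnnotation

log = logging.getLogger(__name__)

_KNOWN_ELEMENTS = {"X", "Y", "2L", "2R", "3L", "3R", "4", "other"}


def _find(path: str, names: tuple[str, ...]) -> str | None:
    for name in names:
        for cand in (name, name + ".gz"):
            full = os.path.join(path, cand)
            if os.path.exists(full):
                return full
    return None


def _read_tsv_column(path: str, column: int = 0) -> list[str]:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()]


def read_counts(path: str) -> CountMatrix:
    """Read a 10x MatrixMarket triplet directory or a gene x sample TSV.

    Both the v2 (``genes.tsv``) and v3 (``features.tsv.gz``) sidecar dialects
    are accepted. In MatrixMarket directories the matrix is genes x barcodes
    (cellranger convention) and is transposed to cells x genes on read. TSV
    input is gene x sample and likewise transposed to samples x genes.
    """
    if os.path.isdir(path):
        mtx = _find(path, ("matrix.mtx",))
        barcodes = _find(path, ("barcodes.tsv",))
        features = _find(path, ("features.tsv", "genes.tsv"))
        if not (mtx and barcodes and features):
            raise FormatError(f"{path} is not a MatrixMarket triplet directory")
        mat = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = _read_tsv_column(features)
        cells = _read_tsv_column(barcodes)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {mat.shape} but sidecars declare "
                f"{len(genes)} genes x {len(cells)} barcodes"
            )
        out = CountMatrix(mat.T.tocsr(), pd.Index(cells), pd.Index(genes))
    else:
        table = pd.read_csv(path, sep="\t", index_col=0)
        out = CountMatrix(
            sp.csr_matrix(table.to_numpy().T),
            pd.Index(table.columns),
            pd.Index(table.index),
        )
    out.validate_raw()
    return out


def write_counts(matrix: CountMatrix, path: str) -> None:
    """Write a MatrixMarket triplet directory readable by :func:`read_counts`."""
    for idx in (matrix.obs_names, matrix.var_names):
        if any("\t" in str(name) for name in idx):
            raise FormatError("ids may not contain tab characters")
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(path, "matrix.mtx"),
        sp.coo_matrix(matrix.X.T),
        field="integer" if matrix.X.dtype.kind in "iu" else "real",
    )
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        fh.writelines(f"{b}\n" for b in matrix.obs_names)
    with open(os.path.join(path, "features.tsv"), "w") as fh:
        fh.writelines(f"{g}\t{g}\tGene Expression\n" for g in matrix.var_names)


def read_gene_map(path: str) -> GeneAnnotation:
    """Read a gene -> chromosome-element TSV.

    Required columns: ``gene_id``, ``element``; optional ``length`` (bp) and
    ``domains`` (comma-separated curated cell types). Elements outside the
    D. melanogaster karyotype are mapped to ``"other"`` with a warning.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "element": str})
    if "gene_id" not in table.columns or "element" not in table.columns:
        raise FormatError("gene map requires gene_id and element columns")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].head(3)
        raise FormatError(f"duplicate gene ids in gene map: {list(dupes)}")
    table = table.set_index("gene_id")
    unknown = ~table["element"].isin(_KNOWN_ELEMENTS)
    if unknown.any():
        log.warning(
            "%d genes on unrecognized elements mapped to 'other'", int(unknown.sum())
        )
        table.loc[unknown, "element"] = "other"
    if "domains" in table.columns:
        table["domains"] = [
            tuple(str(d).split(",")) if pd.notna(d) else ()
            for d in table["domains"]
        ]
    return GeneAnnotation(table)


def normalize(
    matrix: CountMatrix, mode: str = "cpm", lengths: pd.Series | None = None
) -> CountMatrix:
    """Depth-normalize to counts-per-million, optionally length-corrected.

    ``cpm`` scales every row to a total of 10^6. ``length_tpm`` first divides
    each gene by its length in kb, then rescales rows to 10^6 (the bulk TPM
    convention). Rows with zero total stay all-zero and trigger a warning.
    """
    if mode not in ("cpm", "length_tpm"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    X = sp.csr_matrix(matrix.X, dtype=float)
    if mode == "length_tpm":
        if lengths is None:
            raise ValueError("length_tpm requires gene lengths")
        lens = pd.Series(lengths).reindex(matrix.var_names)
        if lens.isna().any():
            raise ValueError("lengths missing for some genes")
        X = X @ sp.diags(1.0 / (lens.to_numpy() / 1e3))
    totals = np.asarray(X.sum(axis=1)).ravel()
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} rows with zero total left all-zero")
    scale = np.divide(1e6, totals, out=np.zeros_like(totals), where=~empty)
    X = sp.diags(scale) @ X
    return CountMatrix(X.tocsr(), matrix.obs_names, matrix.var_names)


def pseudobulk_correlation(
    sc: CountMatrix,
    bulk: CountMatrix,
    bulk_lengths: pd.Series | None = None,
) -> pd.Series:
    """Spearman rho between summed single cells and each bulk sample.

    Single-cell counts are summed over cells and cpm-normalized; bulk samples
    are length-TPM normalized when lengths are given, else cpm. Both sides are
    log10(x+1)-transformed (Spearman is invariant to this, it is kept for
    parity with how such comparisons are usually displayed) and compared on
    the shared gene set.
    """
    shared = sc.var_names.intersection(bulk.var_names)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (need >= 10)")
    summed = np.asarray(sc.subset_var(shared).X.sum(axis=0)).ravel()
    pseudo = CountMatrix(
        sp.csr_matrix(summed[None, :]), pd.Index(["pseudobulk"]), shared
    )
    pseudo_cpm = np.log10(normalize(pseudo, "cpm").X.toarray().ravel() + 1)
    bulk_shared = bulk.subset_var(shared)
    mode = "length_tpm" if bulk_lengths is not None else "cpm"
    bulk_norm = np.log10(
        normalize(bulk_shared, mode, lengths=bulk_lengths).X.toarray() + 1
    )
    rhos = {
        str(sample): float(spearmanr(pseudo_cpm, bulk_norm[i]).statistic)
        for i, sample in enumerate(bulk.obs_names)
    }
    return pd.Series(rhos, name="spearman_rho")
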