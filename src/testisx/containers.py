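"""Shared in-memory containers.

The pipeline passes three objects between stages: a :class:`CountMatrix`
(cells-or-samples x genes, sparse), a :class:`GeneAnnotation` mapping genes to
chromosome elements, and a cell table (plain :class:`pandas.DataFrame` keyed by
barcode, documented in :mod:`testisx.qc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Chromosome elements of the D. melanogaster male karyotype, as units.
ELEMENTS = ("X", "Y", "2L", "2R", "3L", "3R", "4")

#: The gene-rich major autosomal arms used as the ratio denominator.
MAJOR_AUTOSOMES = frozenset({"2L", "2R", "3L", "3R"})


class FormatError(ValueError):
    """Raised when an on-disk input violates its format contract."""


@dataclass
class CountMatrix:
    """A sparse expression matrix with row (cell/sample) and column (gene) ids.

    Rows are observations (cell barcodes for single-cell data, sample names
    for bulk panels); columns are genes. Raw matrices hold non-negative
    integers; normalized matrices (cpm / length-TPM) hold non-negative reals.
    """

    X: sp.csr_matrix
    obs_names: pd.Index
    var_names: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.obs_names = pd.Index(self.obs_names, name="obs")
        self.var_names = pd.Index(self.var_names, name="gene")
        if self.X.shape != (len(self.obs_names), len(self.var_names)):
            raise FormatError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.obs_names)} obs x {len(self.var_names)} var ids"
            )
        for name, idx in (("obs", self.obs_names), ("var", self.var_names)):
            if idx.has_duplicates:
                raise FormatError(f"duplicate {name} ids")
        if self.X.nnz and self.X.data.min() < 0:
            raise FormatError("negative entries in count matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def validate_raw(self) -> None:
        """Check the raw-counts invariant (integral, non-negative)."""
        if self.X.nnz and np.any(self.X.data != np.round(self.X.data)):
            raise FormatError("raw counts must be integers")

    def subset_obs(self, keep) -> "CountMatrix":
        """Rows restricted to a boolean mask, positions, or a list of ids."""
        idx = self._resolve(keep, self.obs_names)
        return CountMatrix(self.X[idx], self.obs_names[idx], self.var_names)

    def subset_var(self, keep) -> "CountMatrix":
        idx = self._resolve(keep, self.var_names)
        return CountMatrix(
            self.X.tocsc()[:, idx].tocsr(), self.obs_names, self.var_names[idx]
        )

    @staticmethod
    def _resolve(keep, index: pd.Index) -> np.ndarray:
        keep = np.asarray(list(keep) if isinstance(keep, (set, frozenset)) else keep)
        if keep.dtype == bool:
            if keep.size != index.size:
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(keep)
        if keep.dtype.kind in "iu":
            return keep
        pos = index.get_indexer(keep)
        if (pos < 0).any():
            missing = keep[pos < 0][:3]
            raise KeyError(f"ids not present: {list(missing)} ...")
        return pos

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.X.copy(),
            obs=pd.DataFrame(index=self.obs_names.astype(str)),
            var=pd.DataFrame(index=self.var_names.astype(str)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X.toarray(), index=self.obs_names, columns=self.var_names
        )


@dataclass
class GeneAnnotation:
    """Per-gene chromosome element, optional length and curated domains.

    ``table`` is indexed by gene id with columns ``element`` (one of
    :data:`ELEMENTS` or ``"other"``), optional ``length`` (bp, > 0) and
    optional ``domains`` (tuple of curated cell types per gene).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise FormatError("duplicate gene ids in annotation")
        if "element" not in t.columns:
            raise FormatError("annotation requires an 'element' column")
        if "length" in t.columns:
            lengths = t["length"].dropna()
            if (lengths <= 0).any():
                raise FormatError("gene lengths must be > 0")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def element(self) -> pd.Series:
        return self.table["element"]

    @property
    def lengths(self) -> pd.Series | None:
        return self.table["length"] if "length" in self.table.columns else None

    def genes_of(self, element: str) -> pd.Index:
        if element not in set(self.element.unique()):
            raise KeyError(f"unknown chromosome element {element!r}")
        return self.table.index[self.element == element]


def new_cell_table(barcodes) -> pd.DataFrame:
    """Fresh QC/label table: one row per barcode, all flags cleared."""
    barcodes = pd.Index(barcodes, name="barcode")
    if barcodes.has_duplicates:
        raise FormatError("duplicate barcodes")
    return pd.DataFrame(
        {
            "cell_type": pd.Series(pd.NA, index=barcodes, dtype="string"),
            "low_quality": False,
            "homotypic_multiplet": False,
            "heterotypic_multiplet": False,
        },
        index=barcodes,
    )
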