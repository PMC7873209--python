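"""Data-driven housekeeping gene sets and curated-expression concordance.

Three nested notions of "widely expressed" are computed: low tissue
specificity in an adult bulk panel (Tau, TSPS) and low cell-type specificity
within the single-cell experiment itself (CTSP, detection in >= 1/3 of
cells). A gene with tau <= 0.5 or TSPS <= 1 is considered not
tissue-specific; CTSP is the most stringent set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix


def expressed_genes(matrix: CountMatrix, min_cells: int = 3) -> pd.Index:
    """Genes detected (count > 0) in at least ``min_cells`` cells."""
    detected = np.asarray((matrix.X > 0).sum(axis=0)).ravel()
    return matrix.var_names[detected >= min_cells]


def _tissue_means(
    panel: CountMatrix, tissues: pd.Series, transform
) -> pd.DataFrame:
    """Per-gene mean of ``transform(expression)`` within each tissue."""
    tissues = pd.Series(tissues).reindex(panel.obs_names)
    if tissues.isna().any():
        raise ValueError("tissue labels missing for some samples")
    if tissues.nunique() < 2:
        raise ValueError("need >= 2 tissues")
    dense = transform(panel.X.toarray())
    frame = pd.DataFrame(dense, index=panel.obs_names, columns=panel.var_names)
    return frame.groupby(tissues.to_numpy()).mean()  # tissues x genes


def compute_tau(
    panel: CountMatrix, tissues: pd.Series, log_transform: bool = True
) -> pd.Series:
    """Tissue-specificity index tau in [0, 1].

    Tissue means x_i (of log2(TPM+1) by default) are scaled by their maximum,
    x_hat_i = x_i / max_i x_i, and tau = sum_i (1 - x_hat_i) / (N - 1):
    0 for a uniform profile, 1 for single-tissue expression. Genes with an
    all-zero profile get NaN. ``panel`` must already be TPM/cpm normalized.
    """
    transform = (lambda x: np.log2(x + 1.0)) if log_transform else (lambda x: x)
    means = _tissue_means(panel, tissues, transform)
    n = means.shape[0]
    mx = means.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = means / mx
    tau = (1.0 - xhat).sum(axis=0) / (n - 1)
    tau[mx <= 0] = np.nan
    return tau.rename("tau")


def compute_tsps(panel: CountMatrix, tissues: pd.Series) -> pd.Series:
    """Tissue specificity score: relative entropy versus a uniform profile.

    With tissue-mean shares p_i = mean_i / sum_i mean_i over N tissues,
    TSPS = sum_i p_i * log2(p_i * N) (zero terms contribute 0). 0 bits for a
    uniform profile, log2(N) for single-tissue expression. Computed on
    linear normalized expression; scale-invariant by construction.
    """
    means = _tissue_means(panel, tissues, lambda x: x)
    n = means.shape[0]
    total = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = means / total
        terms = p * np.log2(p * n)
    tsps = terms.where(p > 0, 0.0).sum(axis=0)
    tsps[total <= 0] = np.nan
    return tsps.rename("tsps")


def compute_ctsp(
    matrix: CountMatrix,
    fraction: float = 1.0 / 3.0,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene detection fraction over QC-passing cells and CTSP membership.

    A gene is a CTSP ("low cell-type specificity") member when it is
    detected (count > 0) in at least ``fraction`` of the cells considered.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mat = matrix if cell_mask is None else matrix.subset_obs(np.asarray(cell_mask))
    detected = np.asarray((mat.X > 0).sum(axis=0)).ravel()
    frac = detected / mat.shape[0]
    return pd.DataFrame(
        {"ctsp_fraction": frac, "ctsp_member": frac >= fraction},
        index=matrix.var_names,
    )


def specificity_table(
    matrix: CountMatrix,
    panel: CountMatrix,
    tissues: pd.Series,
    min_cells: int = 3,
    tau_cutoff: float = 0.5,
    tsps_cutoff: float = 1.0,
    ctsp_fraction: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Combined per-gene table of all membership flags (Table-1 style)."""
    genes = matrix.var_names
    table = pd.DataFrame(index=genes)
    table["expressed"] = genes.isin(expressed_genes(matrix, min_cells))
    ctsp = compute_ctsp(matrix, ctsp_fraction)
    table["ctsp_fraction"] = ctsp["ctsp_fraction"]
    table["ctsp_member"] = ctsp["ctsp_member"] & table["expressed"]
    tau = compute_tau(panel, tissues).reindex(genes)
    tsps = compute_tsps(panel, tissues).reindex(genes)
    table["tau"] = tau
    table["tsps"] = tsps
    table["tau_member"] = (tau <= tau_cutoff) & table["expressed"]
    table["tsps_member"] = (tsps <= tsps_cutoff) & table["expressed"]
    return table


@dataclass
class LineageMap:
    """Ordered developmental chains; each cell type in exactly one chain."""

    chains: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "germline": ("G", "E1", "M1", "L1"),
            "cyst": ("C1", "C2", "C3", "C4"),
            "terminal_epithelium": ("T",),
            "pigment": ("P",),
        }
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chain in self.chains.values():
            if seen & set(chain):
                raise ValueError("cell type in more than one lineage")
            seen |= set(chain)

    def chain_of(self, cell_type: str) -> str:
        for name, chain in self.chains.items():
            if cell_type in chain:
                return name
        raise KeyError(f"unknown cell type {cell_type!r}")

    def position(self, cell_type: str) -> int:
        return self.chains[self.chain_of(cell_type)].index(cell_type)


def concordance_score(
    predicted_biased: set[str],
    predicted_high: set[str],
    curated: set[str],
    lineage: LineageMap | None = None,
) -> int:
    """0-4 overlap score between predicted and curated expression domains.

    4: cell-type-biased expression in exactly the curated types, or (protein
    may lag transcription) curated expression later in the same lineage
    chain than the biased types. 3: highly expressed (not biased) in exactly
    the curated types. 2: biased in the same lineage. 1: highly expressed in
    the same lineage. 0: no overlap.
    """
    lineage = lineage or LineageMap()
    for t in set(predicted_biased) | set(predicted_high) | set(curated):
        lineage.chain_of(t)  # raises on unknown names
    if not curated:
        raise ValueError("curated domain set is empty")

    def chains(types: set[str]) -> set[str]:
        return {lineage.chain_of(t) for t in types}

    if predicted_biased:
        if set(predicted_biased) == set(curated):
            return 4
        biased_chains = chains(set(predicted_biased))
        if len(biased_chains) == 1 and chains(set(curated)) == biased_chains:
            latest_biased = max(lineage.position(t) for t in predicted_biased)
            if all(lineage.position(t) >= latest_biased for t in curated):
                return 4
    if predicted_high and set(predicted_high) == set(curated):
        return 3
    if predicted_biased and chains(set(predicted_biased)) & chains(set(curated)):
        return 2
    if predicted_high and chains(set(predicted_high)) & chains(set(curated)):
        return 1
    return 0
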