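"""Cell selection: low-content filtering, clustering-stability grid search
for homotypic multiplets, and heterotypic multiplet detection by in-silico
mixing of cluster centroids.

Homotypic multiplets (two cells of the same type in one droplet) sit at the
top of the expressed-genes-per-cell distribution, but a hard upper cutoff
risks discarding genuinely high-RNA-content cell types. The grid search
clusters the data under each candidate cutoff and keeps the smallest cutoff
whose clustering is stable (adjusted Rand index against the most permissive
cutoff's clustering) - i.e. removal changed nothing but the multiplets.
Heterotypic multiplets look like intermediate cell types; they are flagged
when an in-silico mixture of two cluster centroids explains a cell's profile
better than any pure centroid does.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .containers import CountMatrix

log = logging.getLogger(__name__)


def expressed_gene_counts(matrix: CountMatrix) -> pd.Series:
    """Number of genes with count > 0, per cell."""
    counts = np.asarray((matrix.X > 0).sum(axis=1)).ravel()
    return pd.Series(counts, index=matrix.obs_names, name="n_genes")


def filter_low_content(matrix: CountMatrix, min_genes: int) -> pd.Series:
    """Flag barcodes expressing fewer than ``min_genes`` genes (likely empty)."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    flags = expressed_gene_counts(matrix) < min_genes
    return flags.rename("low_quality")


def cluster_cells(
    matrix: CountMatrix,
    n_var_genes: int = 2000,
    resolution: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community labels from the standard scRNA-seq recipe.

    Depth-normalize, log1p, select the ``n_var_genes`` most variable genes,
    reduce with PCA, build a kNN graph and partition it by modularity at the
    given resolution. Deterministic for a fixed seed.
    """
    import scanpy as sc

    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 cells to cluster")
    if n_var_genes > matrix.shape[1]:
        warnings.warn("fewer genes than n_var_genes; using all genes")
        n_var_genes = matrix.shape[1]
    adata = matrix.to_anndata()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_var_genes, flavor="seurat")
    adata = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.scale(adata, max_value=10)
    adata.X = np.nan_to_num(adata.X)  # zero-variance genes scale to NaN
    if not np.any(adata.X):  # all cells identical: one trivial cluster
        return np.zeros(matrix.shape[0], dtype=int)
    n_comps = int(min(50, adata.n_obs - 1, adata.n_vars - 1))
    sc.tl.pca(adata, n_comps=max(n_comps, 1), random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=15, random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        key_added="leiden",
        flavor="leidenalg",
    )
    return adata.obs["leiden"].astype(int).to_numpy()


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size < 2:
        raise ValueError("need >= 2 items")
    return float(adjusted_rand_score(a, b))


@dataclass
class GridSearchReport:
    """Outcome of the upper expressed-genes-threshold grid search."""

    thresholds: list[int]  # thresholds actually evaluated
    labels: dict[int, pd.Series]  # threshold -> labels over retained cells
    ari: pd.DataFrame  # pairwise ARI over the common cell set
    removed: dict[int, pd.Index]  # threshold -> barcodes removed
    selected: int  # chosen threshold
    skipped: list[int]  # thresholds with too few retained cells


def select_upper_threshold(
    matrix: CountMatrix,
    thresholds=(4000, 5000, 6000),
    stability: float = 0.95,
    seed: int = 0,
    min_cells: int = 50,
    **cluster_kwargs,
) -> GridSearchReport:
    """Grid-search an upper expressed-genes cutoff for homotypic multiplets.

    Each threshold removes cells whose expressed-gene count exceeds it; the
    retained cells are clustered; labelings are compared by ARI on the cells
    retained at *every* threshold. The smallest threshold whose labeling has
    ARI >= ``stability`` against the most permissive threshold's labeling is
    selected (falling back to the most permissive threshold itself).
    """
    thresholds = sorted(set(int(t) for t in thresholds))
    if len(thresholds) < 2:
        raise ValueError("need >= 2 distinct thresholds")
    n_genes = expressed_gene_counts(matrix)

    usable, skipped, labels, removed = [], [], {}, {}
    for t in thresholds:
        keep = n_genes <= t
        if keep.sum() < min_cells:
            log.warning("threshold %d retains %d cells; skipped", t, keep.sum())
            skipped.append(t)
            continue
        sub = matrix.subset_obs(keep.to_numpy())
        lab = cluster_cells(sub, seed=seed, **cluster_kwargs)
        labels[t] = pd.Series(lab, index=sub.obs_names)
        removed[t] = matrix.obs_names[~keep.to_numpy()]
        usable.append(t)
    if not usable:
        raise ValueError("every threshold retained too few cells")

    common = labels[usable[0]].index
    for t in usable[1:]:
        common = common.intersection(labels[t].index)
    ari = pd.DataFrame(1.0, index=usable, columns=usable)
    for i, t1 in enumerate(usable):
        for t2 in usable[i + 1 :]:
            value = adjusted_rand_index(
                labels[t1].loc[common], labels[t2].loc[common]
            )
            ari.loc[t1, t2] = ari.loc[t2, t1] = value

    reference = usable[-1]  # most permissive
    selected = reference
    for t in usable:
        if ari.loc[t, reference] >= stability:
            selected = t
            break
    return GridSearchReport(
        thresholds=usable,
        labels=labels,
        ari=ari,
        removed=removed,
        selected=selected,
        skipped=skipped,
    )


@dataclass
class MixtureModel:
    """Centroids and pairwise mixtures used for heterotypic detection."""

    centroids: pd.DataFrame  # clusters x genes, log1p cpm over variable genes
    mixtures: pd.DataFrame  # (cluster_a, cluster_b, fraction) x genes
    scores: pd.DataFrame  # per cell: best_pure, best_mixture, margin


def _variable_gene_mask(dense: np.ndarray, n_var_genes: int) -> np.ndarray:
    var = dense.var(axis=0)
    n = min(n_var_genes, dense.shape[1])
    cut = np.sort(var)[-n]
    return var >= cut


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``a`` against every row of ``b``."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return az @ bz.T


def detect_heterotypic(
    matrix: CountMatrix,
    labels,
    fractions=(0.5,),
    margin: float = 0.0,
    n_var_genes: int = 2000,
    min_cluster_frac: float = 0.05,
) -> tuple[pd.Series, MixtureModel]:
    """Flag cells better explained by a two-cluster mixture than any cluster.

    Cluster centroids are mean cpm profiles over the most variable genes;
    a mixture for fraction f of the unordered pair (a, b) is
    log1p(f*centroid_a + (1-f)*centroid_b) - mixing happens on the linear
    scale because a droplet containing two cells sums their transcripts
    linearly. A cell is heterotypic when its best Pearson correlation (in
    log1p space) to any mixture of two distinct clusters exceeds its best
    correlation to any pure centroid by more than ``margin``.

    Clusters holding fewer than ``min_cluster_frac`` of all cells do not
    contribute centroids: a handful of genuinely intermediate profiles can
    split into their own community, and treating that community as a pure
    cell type would hide exactly the cells this step must find. Their
    members are still scored against the remaining centroids.
    """
    labels = np.asarray(labels)
    clusters, sizes = np.unique(labels, return_counts=True)
    if clusters.size < 2:
        raise ValueError("need >= 2 clusters for in-silico mixing")
    big = clusters[sizes >= min_cluster_frac * labels.size]
    if big.size >= 2:
        clusters = big
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError("mixing fractions must be in (0, 1)")

    totals = np.asarray(matrix.X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    cpm = 1e6 * matrix.X.toarray() / totals[:, None]
    dense = np.log1p(cpm)
    keep = _variable_gene_mask(dense, n_var_genes)
    cpm, dense = cpm[:, keep], dense[:, keep]
    gene_index = matrix.var_names[keep]

    lin_centroids = {c: cpm[labels == c].mean(axis=0) for c in clusters}
    centroids = pd.DataFrame(
        np.log1p(np.vstack([lin_centroids[c] for c in clusters])),
        index=pd.Index(clusters, name="cluster"),
        columns=gene_index,
    )
    mix_rows, mix_keys = [], []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            for f in fractions:
                mix_rows.append(
                    np.log1p(f * lin_centroids[a] + (1 - f) * lin_centroids[b])
                )
                mix_keys.append((a, b, f))
    mixtures = pd.DataFrame(
        np.vstack(mix_rows),
        index=pd.MultiIndex.from_tuples(
            mix_keys, names=["cluster_a", "cluster_b", "fraction"]
        ),
        columns=gene_index,
    )

    pure_corr = _corr_rows(dense, centroids.to_numpy())
    mix_corr = _corr_rows(dense, mixtures.to_numpy())
    best_pure = pure_corr.max(axis=1)
    best_mix = mix_corr.max(axis=1)
    flags = pd.Series(
        best_mix - best_pure > margin, index=matrix.obs_names, name="heterotypic"
    )
    scores = pd.DataFrame(
        {
            "best_pure": best_pure,
            "best_mixture": best_mix,
            "margin": best_mix - best_pure,
        },
        index=matrix.obs_names,
    )
    return flags, MixtureModel(centroids=centroids, mixtures=mixtures, scores=scores)
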