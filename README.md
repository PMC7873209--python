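# testisx

Sex-chromosome expression analysis for the *Drosophila melanogaster* larval
testis, built around single-cell RNA-seq. The scientific question: how do the
single X, the single Y, and the two formerly-X 4th chromosomes behave as male
germ cells move from mitotic spermatogonia into meiotic primary
spermatocytes? Somatic cells dosage-compensate the X (X:A expression ratio
near 1 despite one copy); primary spermatocytes inactivate the X and the 4th
(X:A falling toward 0.5) while the Y switches on. This package implements the
downstream statistics that measure those shifts, for computational biologists
who want to apply or scrutinize them.

## What it computes

For each cell *c* and gene set *S*, the gene-count-normalized element ratio

```
R_c = ( Σ_{g ∈ S∩X} cpm_gc / |S∩X| ) / ( Σ_{g ∈ S∩A} cpm_gc / |S∩A| )
```

with A the major autosomal arms {2L, 2R, 3L, 3R}; per-cell sequencing depth
cancels exactly. Around that core:

- **Gene sets** — expressed genes; low tissue-specificity sets from an adult
  bulk panel via τ = Σᵢ(1 − x̂ᵢ)/(N − 1) (on log₂ tissue means, x̂ᵢ = xᵢ/max)
  and TSPS = Σᵢ pᵢ log₂(pᵢ·N) (relative entropy vs a uniform tissue profile);
  and a cell-type-specificity proxy CTSP (genes detected in ≥ 1/3 of cells).
- **Inference** — cell-label permutation calibration of the Mann–Whitney U
  (pairwise and vs size-matched random samples), Benjamini–Hochberg FDR,
  Pearson χ² independence, bootstrap CIs, per-arm sex-bias t-tests, and
  per-cell GSEA running-sum enrichment scores.
- **QC** — empty-barcode filtering; an upper expressed-genes threshold chosen
  by a clustering-stability grid search (adjusted Rand index) to remove
  homotypic multiplets; heterotypic multiplet detection by in-silico mixing
  of cluster centroids.
- **Territory geometry** — volume, iso-surface area and sphericity
  ψ = π^⅓(6V)^⅔ / A of 3D chromosome-territory voxel masks, probe-length and
  copy-number corrected volumes, edge-to-nucleolus distances, and
  background-subtracted Pol-II intensity ratios.
- **Synthetic data** — a generator with known per-(element, cell type) dosage
  regimes (ten testis cell types, seven chromosome elements, negative-
  binomial UMI counts, doublets, a two-sex multi-tissue bulk panel) so every
  stage is testable without any external download.

## Worked example

`analysis/` holds numbered drivers; each regenerates its inputs from the
synthetic generator (seeds fixed in the scripts) and writes tables under
`results/`. For the central readout:

```
$ python analysis/04_cell_ratios.py
median X:A (all expressed genes) along germline then soma:
cell_type
G     0.997
E1    0.698
M1    0.545
L1    0.498
C1    0.996
T     1.000
P     0.987

median Y totals (cpm) per type:
cell_type
C1       0.0
...
G     1382.7
L1    5160.3
M1    5037.8
```

Read: somatic cells (C1, T, P) and spermatogonia (G) sit at X:A ≈ 1 — dosage
compensation of the single X — while the ratio falls through the primary
spermatocyte stages to ≈ 0.5 in late spermatocytes (L1), i.e. expression
from a single uncompensated, largely inactivated X. The Y inverts: near
silent in soma, maximally active in spermatocytes. These are the generator's
configured regimes being recovered by the per-cell pipeline, not assumed
values.

The other drivers: `01` writes the raw synthetic matrices, `02` runs the
multiplet QC, `03` builds the τ/TSPS/CTSP gene-set census per chromosome
element, `05` runs the permutation inference and per-cell GSEA, `06` the
bulk per-arm sex-bias stage, `07` the territory geometry on synthetic masks.

## Layout

```
src/testisx/       library (simulate, io, qc, genesets, cellstats,
                   inference, geometry)
analysis/          numbered narrative drivers
tests/             pytest suite with brute-force oracles
docs/methods.md    model, parameter and design documentation
```
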