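# Methods

## The measurement model

Single-cell expression is sparse and missingness is informative, so no
statistic here aggregates counts across cells before testing. Every measure
is computed per cell, then cell-type effects are assessed on the resulting
per-cell distributions.

**Element ratio.** For gene set S, focal element e and major autosomes
A = {2L, 2R, 3L, 3R}:

    R_c = (Σ_{g∈S∩e} cpm_gc / |S∩e|) / (Σ_{g∈S∩A} cpm_gc / |S∩A|)

The divisors are *set sizes*, not per-cell detected-gene counts: the
normalization must vary with the chosen gene subset but not with a cell's
dropout pattern, otherwise sparse cells would be biased upward. Because cpm
appears in both numerator and denominator, per-cell depth cancels exactly
(this is asserted as an exact test, not a statistical one). Cells with zero
autosomal expression over S are marked invalid rather than given a value.
Ratios are computed on linear cpm; log10(TPM+1) is reserved for display
summaries.

**"TPM" for UMI data** is implemented as counts-per-million with no gene
length term — 3' UMI counts are not length-proportional. Bulk read counts
use length-corrected TPM (counts / kb, rescaled to 10⁶; union-exon style
lengths).

## Gene sets

- *Expressed*: detected (count > 0) in ≥ 3 cells (configurable).
- *Tau*: τ = Σᵢ (1 − x̂ᵢ)/(N − 1) over N tissue means of log₂(TPM+1),
  x̂ᵢ = xᵢ/maxᵢ xᵢ; membership τ ≤ 0.5. The log transform is the common
  convention for Tau; a linear mode exists (`log_transform=False`), under
  which τ is exactly invariant to per-gene scaling.
- *TSPS*: relative entropy of the linear tissue-mean shares versus uniform,
  Σᵢ pᵢ log₂(pᵢ N); membership TSPS ≤ 1. Scale-invariant by construction.
  Tissue means pool the two sexes by default; a per-sex option exists.
- *CTSP*: detected in ≥ 1/3 of QC-passing cells; "expressed in a cell" means
  count > 0, with no minimum UMI.

All-zero genes get missing (NaN) τ/TSPS rather than a value.

## Permutation inference

The pairwise test computes the Mann–Whitney U between two cell types, then
shuffles the pooled labels n_iter times (default 10,000; drivers use 2,000
at desk scale). "More extreme" is two-sided on |U − E[U]|, E[U] = n_a n_b/2;
the add-one estimator (1 + #extreme)/(n_iter + 1) keeps the p-value valid
and bounded below by 1/(n_iter+1). Permutations draw from a generator keyed
by (seed, stream), so results are reproducible and independent of execution
order.

The mean-comparison variant draws, per iteration, a uniform random sample of
cells the same size as the focal type and records the fraction of iterations
whose Mann–Whitney p falls at or below α (default 0.01). A type is declared
different when that fraction reaches 0.95. This aggregation rule is a
design decision: the alternative reading ("average p") is a proportion, not
a calibrated p-value, so the explicit fraction-plus-threshold rule is
documented instead of presented as canonical.

The U statistic itself uses the exact null for small untied samples and the
normal approximation with tie and continuity corrections otherwise
(scipy's switch), which the tests verify against full enumeration at n ≤ 6.

## Multiplet QC

Homotypic multiplets ride the top of the expressed-genes-per-cell
distribution. The grid search clusters the data under each candidate upper
threshold (log-normalize → 2,000 most variable genes → PCA → kNN graph →
Leiden at resolution 0.3) and compares labelings by adjusted Rand index on
the cells retained at every threshold. "Did not drastically change
clustering" is operationalized as ARI ≥ 0.95 against the most permissive
threshold; the smallest threshold passing is selected. The rule is monotone
in the stability parameter. Default thresholds are [4000, 5000, 6000]
expressed genes (real-data scale); runs on the synthetic data use values
scaled to its 1,242-gene universe.

Heterotypic multiplets look like intermediate cell types. Cluster centroids
are mean cpm profiles over the variable genes; mixtures are formed on the
*linear* scale (a droplet sums transcripts linearly) and compared in
log1p space by Pearson correlation. A cell is flagged when its best mixture
correlation beats its best pure-centroid correlation by more than the margin
(default 0). Clusters holding < 5% of cells contribute no centroids: a
clump of genuinely intermediate profiles can form its own community, and
treating it as a pure type would hide exactly the cells this step exists to
find. Their members are still scored.

## Per-cell GSEA

Genes are ranked per cell by expression (descending, ties broken by gene
id). Set members add |expr|^w normalized by the in-set total; non-members
subtract 1/(N − |S|); the enrichment score is the running sum's signed
maximum deviation, in [−1, 1]. Default weight 1 (weighted
Kolmogorov–Smirnov form); weight 0 gives the classic KS walk. If every set
member has zero expression in a cell, hit increments fall back to uniform.

## Bulk sex-bias stage

Per sample and element: mean TPM over the element's expressed genes. Per
element: percentile-bootstrap 95% CI of the per-sex mean, two-sided Welch
t-test male vs female, BH correction across elements; an element is flagged
male-reduced at q ≤ 0.01 with male mean below female. Differential sex-bias
labels per gene are consumed from input when available; the built-in
`welch_sex_de` (per-gene Welch t on log₂(TPM+1), BH, 2-fold floor) is a
deliberately simple stand-in labeler for the χ² class-by-element test.

## Territory geometry

Masks are binary voxel grids with physical voxel sizes (anisotropy
respected). Volume is voxel counting. Surface area triangulates the 0.5
iso-surface after Gaussian smoothing (σ = 0.8 voxels): the raw staircase
surface overestimates smooth-shape area by ~9% at any resolution, which
would deflate sphericity ψ = π^⅓(6V)^⅔/A systematically; with smoothing a
digitized ball of radius ≥ 10 voxels is within ~1–2% of analytic V and A
and ψ ≤ 1.02. The cost is corner rounding on faceted shapes — territory
masks are blob-like, and σ = 0 restores the raw surface. Edge-to-reference
distance is the minimum physical distance from a mask's boundary voxels to
any voxel of the reference (0 on contact). The copy-number-corrected volume
(V / Mb / copies) is emitted alongside the uncorrected value because the
assumption that volume scales with copy number is of limited validity.
Intensity ratios integrate (signal − mean background) over (total − mean
background) per mask; non-positive denominators yield missing values with a
warning rather than a number.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes — it
is the test bed, not a model of any real library's noise in full.

- **Elements**: X (200 genes, 1 copy), Y (12, 1), 2L/2R/3L/3R (250 each, 2),
  4 (30, 2). Gene-poor Y and 4 mirror the real karyotype at ~1/10 scale.
- **Cell types**: ten types in germline (G → E1 → M1 → L1) and somatic
  (C1–C4, T, P) lineages, sizes proportional to the study's cluster sizes,
  rescaled to ~8,000 cells.
- **Dosage regimes** (per-copy multipliers m_{e,t}; the ground truth):
  X = 2.0 in soma and spermatogonia (compensation), 1.4/1.1/1.0 through
  E1/M1/L1 (progressive inactivation); 4th = 1.0 except 0.85 in M1/L1;
  Y = 0.05 in soma, 0.3 in G, 1.0 in spermatocytes. Expected ratio:
  copies·m / 2. The intermediate E1/M1 levels are placeholders for a
  qualitative trajectory — no quantitative anchor exists for them — and are
  exposed in the config.
- **Rates**: per-gene log-normal(0, 0.8) base rates; 25% of X genes, 30% of
  autosomal genes and no Y genes are "broad" (active in every type);
  remaining genes are active in one type (plus basal activity 5·10⁻⁴
  elsewhere), which is what separates types for clustering. 5% of a type's
  active genes get a ~3-fold marker boost. Within each cell type, every
  (element × broad-flag) group's mean rate is rescaled to exactly
  copies·m_{e,t}: which genes are active still differs between types, but
  the element-level means — hence the expected ratios — are pinned to the
  configured regime instead of the luck of a finite gene draw. Without this
  standardization a single high-rate gene entering or leaving a subset can
  shift an element mean by >10%.
- **Counts**: depth log-normal(log 2500, 0.4), gamma–Poisson
  (negative-binomial, dispersion 10; Poisson available). No ambient RNA,
  batch, or cell-cycle structure is simulated — passing tests therefore
  show correctness of the statistics under clean dosage regimes, not
  robustness to those artifacts.
- **Doublets**: appended barcodes summing two random cells (truth records
  constituents; heterotypic iff the types differ). `balanced=True` thins
  the deeper constituent to equal depth, producing the 50:50 mixtures used
  when benchmarking mixture detection.
- **Bulk panel**: same gene program over 8 tissues × 2 sexes × 4 replicates;
  broad genes active everywhere, restricted genes in 1–2 tissues; optional
  per-gene sex-biased fold changes and a chromosome-wide male X factor for
  the sex-bias stage.

Determinism: all draws run through streams keyed by (seed, stream-id);
identical configs give byte-identical outputs.

## Problem sizes in the drivers and tests

The default dataset is ~8,000 cells × 1,242 genes; permutation drivers use
2,000 iterations; the calibration study runs 500 null replicates of
200-vs-200 cells at 2,000 iterations. These sizes were chosen so a complete
run stays in the minutes range on a laptop while keeping the binomial
uncertainty of every calibration check well inside its acceptance band.

## Known limitations

- The generator's restricted genes are single-type; real marker programs
  are graded along lineages.
- Tau/TSPS defaults (log vs linear input) follow common convention but both
  modes are exposed because usage varies across the literature.
- The heterotypic detector assumes doublet *pairs* dominate; triplets are
  neither simulated nor specifically detected.
- Territory metrics are validated on synthetic shapes only; no real image
  stacks ship with the project.
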