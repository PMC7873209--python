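"""Synthetic larval-testis data with known sex-chromosome dosage regimes.

The generator emulates the statistical structure the downstream analysis
assumes: ten cell types in germline (G -> E1 -> M1 -> L1) and somatic
(C1-C4, T, P) lineages, genes on the seven chromosome elements of the male
karyotype (X, Y, 2L, 2R, 3L, 3R, 4), per-(element, cell type) transcription
regimes, overdispersed UMI counts, optional doublets, and a two-sex
multi-tissue bulk panel.

The dosage regimes are the generative ground truth: the expected per-cell
expression ratio of element ``e`` against the major autosomes in cell type
``t`` is ``copies_e * m_{e,t} / (2 * 1)`` where ``m`` is the per-copy rate
multiplier (major-autosome multiplier fixed at 1). The defaults encode full
somatic and spermatogonial X compensation (m=2 on one copy -> X:A of 1),
progressive X inactivation through the primary-spermatocyte stages
(X:A -> 0.5 in L1), mild late 4th repression, and a Y that is nearly silent
in soma but fully active in spermatocytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, GeneAnnotation, new_cell_table

GERMLINE_CHAIN = ("G", "E1", "M1", "L1")
SOMA_TYPES = ("C1", "C2", "C3", "C4", "T", "P")
SPERMATOCYTES = ("E1", "M1", "L1")

# Haploid gene counts per element, loosely scaled down from the fly genome's
# element sizes (X gene-rich, Y and 4 gene-poor), and male copy numbers.
DEFAULT_ELEMENTS = (
    ("X", 200, 1),
    ("Y", 12, 1),
    ("2L", 250, 2),
    ("2R", 250, 2),
    ("3L", 250, 2),
    ("3R", 250, 2),
    ("4", 30, 2),
)

# Cell-type sizes proportional to the study's reported cluster sizes
# (18,965 cells total) rescaled to an ~8,000-cell desk-scale dataset.
DEFAULT_CELL_TYPES = (
    ("G", "germline", 449),
    ("E1", "germline", 534),
    ("M1", "germline", 1928),
    ("L1", "germline", 1125),
    ("C1", "soma", 1714),
    ("C2", "soma", 519),
    ("C3", "soma", 384),
    ("C4", "soma", 399),
    ("T", "soma", 582),
    ("P", "soma", 366),
)


def default_dosage() -> dict[tuple[str, str], float]:
    """Per-copy rate multipliers m_{e,t} for the default regimes."""
    m: dict[tuple[str, str], float] = {}
    for t in SOMA_TYPES:
        m[("X", t)] = 2.0
        m[("4", t)] = 1.0
        m[("Y", t)] = 0.05
    m[("X", "G")] = 2.0
    m[("X", "E1")] = 1.4
    m[("X", "M1")] = 1.1
    m[("X", "L1")] = 1.0
    m[("4", "G")] = 1.0
    m[("4", "E1")] = 1.0
    m[("4", "M1")] = 0.85
    m[("4", "L1")] = 0.85
    m[("Y", "G")] = 0.3
    for t in SPERMATOCYTES:
        m[("Y", t)] = 1.0
    return m


def default_broad_fraction() -> dict[str, float]:
    # Y carries no widely expressed genes under any metric.
    return {"X": 0.25, "Y": 0.0, "2L": 0.3, "2R": 0.3, "3L": 0.3, "3R": 0.3, "4": 0.3}


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Full description of one synthetic experiment.

    Parameters with biological meaning:

    elements
        ``(name, gene_count, male_copy_number)`` triples.
    cell_types
        ``(name, lineage, n_cells)`` triples; lineage in {germline, soma}.
    dosage
        ``(element, cell_type) -> m`` per-copy rate multipliers; missing
        pairs default to 1 (the major-autosome baseline).
    gene_rate_params
        (mu, sigma) of the log-normal base transcription rate lambda_g.
    libsize_params
        (mu, sigma) of the log-normal cell depth L_c (UMIs per cell).
    broad_fraction
        per-element fraction of genes active in every cell type.
    marker_fraction / marker_boost_params
        per cell type, fraction of its active genes boosted, and the
        log-normal fold-boost distribution.
    basal_activity
        relative rate of a restricted gene outside its home cell types
        (low, non-zero basal transcription).
    dispersion
        negative-binomial size parameter; ``None`` means Poisson.
    """

    elements: tuple = DEFAULT_ELEMENTS
    cell_types: tuple = DEFAULT_CELL_TYPES
    dosage: dict = field(default_factory=default_dosage)
    gene_rate_params: tuple[float, float] = (0.0, 0.8)
    libsize_params: tuple[float, float] = (np.log(2500.0), 0.4)
    broad_fraction: dict = field(default_factory=default_broad_fraction)
    restricted_types_max: int = 1
    marker_fraction: float = 0.05
    marker_boost_params: tuple[float, float] = (np.log(3.0), 0.3)
    basal_activity: float = 0.0005
    dispersion: float | None = 10.0
    doublet_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        names = [e[0] for e in self.elements]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate element names")
        for name, n_genes, copies in self.elements:
            if n_genes <= 0:
                raise ConfigError(f"element {name!r} has {n_genes} genes (need > 0)")
            if copies not in (0, 1, 2):
                raise ConfigError(f"copy number {copies} for {name!r} not in {{0,1,2}}")
        types = [t[0] for t in self.cell_types]
        if len(set(types)) != len(types):
            raise ConfigError("duplicate cell-type names")
        for t, lineage, n in self.cell_types:
            if lineage not in ("germline", "soma"):
                raise ConfigError(f"unknown lineage {lineage!r} for type {t!r}")
            if n <= 0:
                raise ConfigError(f"cell type {t!r} has {n} cells")
        for (e, t), m in self.dosage.items():
            if e not in names:
                raise ConfigError(f"dosage references unknown element {e!r}")
            if t not in types:
                raise ConfigError(f"dosage references unknown cell type {t!r}")
            if m < 0:
                raise ConfigError("dosage multipliers must be >= 0")
        if not 0 <= self.doublet_rate < 1:
            raise ConfigError("doublet_rate must be in [0, 1)")

    @property
    def type_names(self) -> list[str]:
        return [t[0] for t in self.cell_types]

    @property
    def element_names(self) -> list[str]:
        return [e[0] for e in self.elements]

    def copies(self, element: str) -> int:
        return {e[0]: e[2] for e in self.elements}[element]

    def multiplier(self, element: str, cell_type: str) -> float:
        return self.dosage.get((element, cell_type), 1.0)

    def expected_ratio(self, element: str, cell_type: str) -> float:
        """SimTruth expected element:A per-gene expression ratio."""
        return (self.copies(element) * self.multiplier(element, cell_type)) / 2.0


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic experiment."""

    cells: pd.DataFrame  # barcode-indexed: cell_type, doublet, constituents
    genes: pd.DataFrame  # gene-indexed: element, broad, base_rate, active_types
    expected_ratio: pd.DataFrame  # (element x cell_type) expected e:A ratio

    def heterotypic(self) -> pd.Series:
        """True where a barcode is a doublet of two *different* cell types."""
        const = self.cells["constituents"]
        return self.cells["doublet"] & const.map(
            lambda c: isinstance(c, tuple) and len(set(c)) > 1
        )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def generate_annotation(config: SimConfig) -> GeneAnnotation:
    """One record per gene: element membership plus a log-normal gene length."""
    config.validate()
    rng = _rng(config, 0)
    records = []
    for name, n_genes, _ in config.elements:
        for i in range(n_genes):
            records.append((f"{name}.g{i:04d}", name))
    table = pd.DataFrame(records, columns=["gene_id", "element"]).set_index("gene_id")
    table["length"] = np.round(rng.lognormal(np.log(2000.0), 0.5, len(table))).astype(
        int
    ) + 100
    return GeneAnnotation(table)


def _gene_program(config: SimConfig, annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-gene base rates, broad flags, home cell types and marker boosts.

    Base rates are drawn log-normal and then standardized so every
    (element x broad) stratum has the same mean rate; this pins the expected
    element:A ratio to the configured dosage regime rather than to the luck
    of the rate draw.
    """
    rng = _rng(config, 1)
    genes = annotation.genes
    element = annotation.element
    n = len(genes)
    rates = rng.lognormal(*config.gene_rate_params, n)
    target = float(np.exp(config.gene_rate_params[0] + config.gene_rate_params[1] ** 2 / 2))

    broad = np.zeros(n, dtype=bool)
    for el in config.element_names:
        idx = np.flatnonzero(element.to_numpy() == el)
        frac = config.broad_fraction.get(el, 0.3)
        k = int(round(frac * idx.size))
        if k:
            broad[rng.choice(idx, size=k, replace=False)] = True

    for el in config.element_names:
        for flag in (True, False):
            stratum = (element.to_numpy() == el) & (broad == flag)
            if stratum.sum() >= 2:
                rates[stratum] *= target / rates[stratum].mean()

    types = config.type_names
    active_types = []
    for i in range(n):
        if broad[i]:
            active_types.append(tuple(types))
        else:
            k = rng.integers(1, config.restricted_types_max + 1)
            active_types.append(tuple(rng.choice(types, size=k, replace=False)))

    boosts = pd.DataFrame(1.0, index=genes, columns=types)
    for t in types:
        active_in_t = np.array([t in a for a in active_types])
        idx = np.flatnonzero(active_in_t)
        k = int(round(config.marker_fraction * idx.size))
        if k:
            chosen = rng.choice(idx, size=k, replace=False)
            boosts.iloc[chosen, boosts.columns.get_loc(t)] = rng.lognormal(
                *config.marker_boost_params, k
            )

    return pd.DataFrame(
        {
            "element": element.to_numpy(),
            "broad": broad,
            "base_rate": rates,
            "active_types": active_types,
        },
        index=genes,
    ).join(boosts.add_prefix("boost_"))


def _type_rate_matrix(config: SimConfig, program: pd.DataFrame) -> pd.DataFrame:
    """Relative transcription rate of each gene in each cell type.

    After combining base rate, copy number, dosage multiplier, activity and
    marker boost, every (element x broad-flag) gene group is rescaled within
    each cell type so its mean rate equals exactly
    ``copies_e * m_{e,t}``. Which genes are active still differs between
    types (that is the clustering signal); the rescaling pins the per-type
    element means - and hence the expected element:A ratios - to the
    configured dosage regime instead of the luck of the gene draw.
    """
    types = config.type_names
    rates = pd.DataFrame(index=program.index, columns=types, dtype=float)
    element = program["element"].to_numpy()
    broad = program["broad"].to_numpy()
    for t in types:
        mult = program["element"].map(
            lambda e, t=t: config.copies(e) * config.multiplier(e, t)
        )
        active = program["active_types"].map(lambda a, t=t: t in a)
        activity = np.where(active, 1.0, config.basal_activity)
        col = (
            program["base_rate"] * mult * activity * program[f"boost_{t}"]
        ).to_numpy()
        for el in config.element_names:
            target = config.copies(el) * config.multiplier(el, t)
            for flag in (True, False):
                group = (element == el) & (broad == flag)
                mean = col[group].mean() if group.any() else 0.0
                if mean > 0:
                    col[group] *= target / mean
        rates[t] = col
    return rates


def generate_cells(
    config: SimConfig, annotation: GeneAnnotation
) -> tuple[CountMatrix, SimTruth]:
    """Draw the single-cell UMI matrix and its ground truth.

    Per cell of type ``t``, gene ``g`` receives a negative-binomial (or
    Poisson) count with mean ``L_c * rate_{g,t} / sum_g rate_{g,t}`` where
    ``rate_{g,t} = lambda_g * copies * m_{e,t} * activity * boost``.
    """
    config.validate()
    if list(annotation.genes) != list(generate_annotation(config).genes):
        raise ConfigError("annotation does not match config")
    program = _gene_program(config, annotation)
    rate = _type_rate_matrix(config, program)
    rng = _rng(config, 2)

    blocks, barcodes, labels = [], [], []
    for t, _lineage, n_cells in config.cell_types:
        p = rate[t].to_numpy()
        p = p / p.sum()
        depths = np.maximum(
            np.round(rng.lognormal(*config.libsize_params, n_cells)), 100.0
        )
        mu = depths[:, None] * p[None, :]
        if config.dispersion is None:
            counts = rng.poisson(mu)
        else:
            lam = rng.gamma(config.dispersion, mu / config.dispersion)
            counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        barcodes.extend(f"{t}-{i:05d}" for i in range(n_cells))
        labels.extend([t] * n_cells)

    matrix = CountMatrix(
        sp.vstack(blocks).tocsr(), pd.Index(barcodes), annotation.genes
    )
    cells = new_cell_table(barcodes)
    cells["cell_type"] = pd.array(labels, dtype="string")
    cells["doublet"] = False
    cells["constituents"] = None

    ratios = pd.DataFrame(
        {
            t: [config.expected_ratio(e, t) for e in config.element_names]
            for t in config.type_names
        },
        index=pd.Index(config.element_names, name="element"),
    )
    truth = SimTruth(cells=cells, genes=program, expected_ratio=ratios)
    if config.doublet_rate > 0:
        matrix, truth = inject_doublets(
            matrix, truth, config.doublet_rate, seed=config.seed
        )
    return matrix, truth


def inject_doublets(
    matrix: CountMatrix,
    truth: SimTruth,
    rate: float,
    seed: int,
    balanced: bool = False,
) -> tuple[CountMatrix, SimTruth]:
    """Append ``round(rate * n_cells)`` barcodes summing two random cells.

    With ``balanced=True`` the deeper constituent is binomially thinned to
    the shallower one's depth before summing, yielding 50:50 mixtures; the
    default sums the cells as captured (depth-skewed mixtures).
    """
    if not 0 <= rate < 1:
        raise ValueError("doublet rate must be in [0, 1)")
    n = matrix.shape[0]
    k = int(round(rate * n))
    if k == 0:
        return matrix, truth
    rng = np.random.default_rng([int(seed), 3])
    pairs = np.array([rng.choice(n, size=2, replace=False) for _ in range(k)])
    if balanced:
        depths = np.asarray(matrix.X.sum(axis=1)).ravel()
        rows = []
        for a, b in pairs:
            va = matrix.X[a].toarray().ravel()
            vb = matrix.X[b].toarray().ravel()
            if depths[a] > depths[b]:
                va = rng.binomial(va.astype(int), depths[b] / depths[a])
            elif depths[b] > depths[a]:
                vb = rng.binomial(vb.astype(int), depths[a] / depths[b])
            rows.append(va + vb)
        summed = sp.csr_matrix(np.vstack(rows))
    else:
        summed = matrix.X[pairs[:, 0]] + matrix.X[pairs[:, 1]]
    dbl_barcodes = [f"DBL-{i:05d}" for i in range(k)]
    out = CountMatrix(
        sp.vstack([matrix.X, sp.csr_matrix(summed)]).tocsr(),
        matrix.obs_names.append(pd.Index(dbl_barcodes)),
        matrix.var_names,
    )
    types = truth.cells["cell_type"]
    extra = new_cell_table(dbl_barcodes)
    extra["cell_type"] = pd.NA
    extra["doublet"] = True
    extra["constituents"] = [
        (str(types.iloc[a]), str(types.iloc[b])) for a, b in pairs
    ]
    extra["constituent_barcodes"] = [
        (str(matrix.obs_names[a]), str(matrix.obs_names[b])) for a, b in pairs
    ]
    cells = pd.concat([truth.cells, extra])
    return out, SimTruth(cells=cells, genes=truth.genes, expected_ratio=truth.expected_ratio)


@dataclass
class BulkPanel:
    """A synthetic two-sex multi-tissue bulk panel plus its ground truth."""

    counts: CountMatrix  # samples x genes, raw read counts
    meta: pd.DataFrame  # sample-indexed: tissue, sex, replicate
    lengths: pd.Series  # gene length in bp (for length-TPM)
    sex_bias_truth: pd.Series  # per gene: {male, female, unbiased}


def generate_bulk_panel(
    config: SimConfig,
    n_tissues: int = 8,
    n_reps: int = 4,
    seed: int | None = None,
    male_x_factor: float = 1.0,
    sex_biased_fraction: float = 0.1,
    sex_fold: float = 4.0,
    depth: float = 2e6,
) -> BulkPanel:
    """A two-sex multi-tissue bulk read-count panel over the same genes.

    Broad genes are expressed in every tissue at similar levels; restricted
    genes are concentrated in 1-2 tissues. ``sex_biased_fraction`` of genes
    per direction carry a ``sex_fold`` change; ``male_x_factor`` multiplies
    X-linked genes in male samples (1.0 = no chromosome-wide sex effect).
    """
    if n_tissues < 2 or n_reps < 2:
        raise ValueError("need n_tissues >= 2 and n_reps >= 2")
    config.validate()
    annotation = generate_annotation(config)
    program = _gene_program(config, annotation)
    rng = np.random.default_rng(
        [int(config.seed if seed is None else seed), 4]
    )
    genes = program.index
    n_genes = len(genes)
    tissues = [f"tissue{i + 1:02d}" for i in range(n_tissues)]

    active = np.full((n_genes, n_tissues), config.basal_activity)
    broad = program["broad"].to_numpy()
    active[broad, :] = 1.0
    for i in np.flatnonzero(~broad):
        k = rng.integers(1, config.restricted_types_max + 1)
        active[i, rng.choice(n_tissues, size=k, replace=False)] = 1.0

    male_fc = np.ones(n_genes)
    female_fc = np.ones(n_genes)
    n_biased = int(round(sex_biased_fraction * n_genes))
    biased = rng.choice(n_genes, size=2 * n_biased, replace=False)
    male_fc[biased[:n_biased]] = sex_fold
    female_fc[biased[n_biased:]] = sex_fold
    sex_bias_truth = np.array(["unbiased"] * n_genes, dtype=object)
    sex_bias_truth[biased[:n_biased]] = "male"
    sex_bias_truth[biased[n_biased:]] = "female"

    is_x = (program["element"] == "X").to_numpy()
    lengths_kb = annotation.lengths.to_numpy() / 1e3

    rows, meta = [], []
    for tissue_idx, tissue in enumerate(tissues):
        base = program["base_rate"].to_numpy() * active[:, tissue_idx]
        for sex in ("male", "female"):
            rate = base * (male_fc if sex == "male" else female_fc)
            if sex == "male":
                rate = rate * np.where(is_x, male_x_factor, 1.0)
            read_rate = rate * lengths_kb  # reads scale with transcript length
            p = read_rate / read_rate.sum()
            for rep in range(n_reps):
                d = depth * rng.lognormal(0.0, 0.1)
                mu = d * p
                lam = rng.gamma(20.0, mu / 20.0)
                rows.append(rng.poisson(lam))
                meta.append((f"{tissue}_{sex}_r{rep + 1}", tissue, sex, rep + 1))

    meta_df = pd.DataFrame(
        meta, columns=["sample", "tissue", "sex", "replicate"]
    ).set_index("sample")
    counts = CountMatrix(
        sp.csr_matrix(np.vstack(rows)), pd.Index(meta_df.index), genes
    )
    return BulkPanel(
        counts=counts,
        meta=meta_df,
        lengths=annotation.lengths.copy(),
        sex_bias_truth=pd.Series(sex_bias_truth, index=genes, name="sex_bias"),
    )


def write_truth(truth: SimTruth, path_prefix: str) -> None:
    """Persist truth tables as TSV (constituents joined with '+')."""
    cells = truth.cells.copy()
    cells["constituents"] = cells["constituents"].map(
        lambda c: "+".join(c) if isinstance(c, tuple) else ""
    )
    cells.to_csv(path_prefix + ".cells.tsv", sep="\t")
    genes = truth.genes.copy()
    genes["active_types"] = genes["active_types"].map(",".join)
    genes.to_csv(path_prefix + ".genes.tsv", sep="\t")
    truth.expected_ratio.to_csv(path_prefix + ".expected_ratio.tsv", sep="\t")
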