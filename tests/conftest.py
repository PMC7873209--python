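import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import testisx as tx

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_dataset():
    """The default ~8,000-cell synthetic testis experiment (fixed seed)."""
    cfg = tx.SimConfig(seed=0)
    annotation = tx.generate_annotation(cfg)
    matrix, truth = tx.generate_cells(cfg, annotation)
    norm = tx.normalize(matrix, "cpm")
    return cfg, annotation, matrix, truth, norm


@pytest.fixture(scope="session")
def two_type_dataset():
    """Two strongly separated cell types, 500 cells each, no dosage regime."""
    cfg = tx.SimConfig(
        cell_types=(("A", "germline", 500), ("B", "soma", 500)),
        dosage={},
        seed=1,
    )
    annotation = tx.generate_annotation(cfg)
    matrix, truth = tx.generate_cells(cfg, annotation)
    return cfg, annotation, matrix, truth


@pytest.fixture(scope="session")
def bulk_x_halved():
    """Bulk panel whose only sex effect is halved X expression in males."""
    cfg = tx.SimConfig(seed=2)
    panel = tx.generate_bulk_panel(
        cfg, male_x_factor=0.5, sex_biased_fraction=0.0
    )
    annotation = tx.generate_annotation(cfg)
    tpm = tx.normalize(panel.counts, "length_tpm", lengths=panel.lengths)
    return panel, annotation, tpm


def make_counts(array, cells=None, genes=None) -> tx.CountMatrix:
    array = np.asarray(array)
    cells = cells or [f"c{i}" for i in range(array.shape[0])]
    genes = genes or [f"g{j}" for j in range(array.shape[1])]
    return tx.CountMatrix(sp.csr_matrix(array), pd.Index(cells), pd.Index(genes))


def make_annotation(elements, lengths=None, genes=None) -> tx.GeneAnnotation:
    genes = genes or [f"g{j}" for j in range(len(elements))]
    table = pd.DataFrame({"element": elements}, index=pd.Index(genes, name="gene_id"))
    if lengths is not None:
        table["length"] = lengths
    return tx.GeneAnnotation(table)
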