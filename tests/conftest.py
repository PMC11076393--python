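from __future__ import annotations

import functools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from bspai.core_io import CellMatrix
from bspai.features import PairFeaturizer
from bspai.labeling import PairDataset, aggregate_pair_labels, build_dataset
from bspai.simulate import SimConfig, SyntheticStudy, simulate_study


def make_matrix(
    values,
    cell_types=None,
    tissues=None,
    patients=None,
    genes=None,
) -> CellMatrix:
    """Build a small annotated expression matrix from a dense array."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    cell_types = list(cell_types) if cell_types is not None else ["T"] * n_cells
    tissues = list(tissues) if tissues is not None else ["tumor"] * n_cells
    patients = list(patients) if patients is not None else ["P1"] * n_cells
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(n_genes)]
    obs = pd.DataFrame(
        {"cell_type": cell_types, "tissue": tissues, "patient": patients},
        index=[f"c{i}" for i in range(n_cells)],
    )
    adata = AnnData(
        X=sp.csr_matrix(values), obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    return CellMatrix(adata)


def random_matrix(rng, n_cells=None, n_genes=None, n_types=3, with_normal=True) -> CellMatrix:
    """Random small fixture: counts <= 50 cells x 10 genes with mixed annotations."""
    n_cells = n_cells or int(rng.integers(6, 51))
    n_genes = n_genes or int(rng.integers(2, 11))
    values = rng.poisson(1.5, size=(n_cells, n_genes)).astype(float)
    types = [f"ct{int(k)}" for k in rng.integers(0, n_types, n_cells)]
    if with_normal:
        tissues = ["tumor" if rng.random() < 0.6 else "normal" for _ in range(n_cells)]
        # guarantee both compartments
        tissues[0], tissues[1] = "tumor", "normal"
    else:
        tissues = ["tumor"] * n_cells
    return make_matrix(values, cell_types=types, tissues=tissues)


@functools.lru_cache(maxsize=16)
def study_for_seed(seed: int, **overrides) -> SyntheticStudy:
    return simulate_study(SimConfig(seed=seed, **overrides))


@functools.lru_cache(maxsize=16)
def dataset_for_seed(seed: int) -> PairDataset:
    """Full default-conditions pipeline: simulate, featurize, label, fold-assign."""
    study = study_for_seed(seed)
    featurizer = PairFeaturizer()
    featurizer.fit(study.matrix, pathways=study.pathways, embeddings=study.embeddings)
    X = featurizer.transform(study.labeled_pairs)
    labels = aggregate_pair_labels(study.drug_records)
    return build_dataset(labels, X, cv_folds=5, seed=seed)


@pytest.fixture(scope="session")
def default_study() -> SyntheticStudy:
    return study_for_seed(42)


@pytest.fixture(scope="session")
def default_dataset() -> PairDataset:
    return dataset_for_seed(42)
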