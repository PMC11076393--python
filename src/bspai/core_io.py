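"""Readers, writers and the annotated expression-matrix container.

File formats are the plain-text single-cell and annotation dialects the rest
of the package consumes:

* expression: MatrixMarket triplet (cells x genes) + ``genes.tsv`` +
  ``barcodes.tsv`` + ``cell_meta.tsv`` (columns cell_id, cell_type, tissue,
  patient; tissue in {tumor, normal});
* drug clinical-progress table (TSV or XLSX, columns drug, target_a,
  target_b, clinical_progress);
* GMT pathway gene sets; embedding TSV (gene then n floats); plain gene list.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .types import DrugRecord, GenePair, GeneEmbeddingTable, PathwayDB

logger = logging.getLogger("bspai")

VALID_TISSUES = ("tumor", "normal")

META_COLUMNS = ("cell_id", "cell_type", "tissue", "patient")


class CellMatrix:
    """Sparse non-negative cells x genes expression with per-cell annotations.

    Thin wrapper over :class:`anndata.AnnData`; ``obs`` carries ``cell_type``,
    ``tissue`` (tumor/normal, may be missing for some cells) and ``patient``.
    """

    def __init__(self, adata: AnnData):
        X = adata.X
        if X is None:
            raise ValueError("expression matrix is missing")
        if not sp.issparse(X):
            adata.X = sp.csr_matrix(np.asarray(X, dtype=np.float64))
        if adata.X.size and adata.X.min() < 0:
            raise ValueError("expression matrix contains negative entries")
        for col in ("cell_type", "tissue", "patient"):
            if col not in adata.obs.columns:
                raise ValueError(f"per-cell metadata is missing column {col!r}")
        bad = ~adata.obs["tissue"].isin(VALID_TISSUES) & adata.obs["tissue"].notna()
        if bad.any():
            row = adata.obs.index[bad][0]
            raise ValueError(
                f"tissue value {adata.obs.loc[row, 'tissue']!r} for cell {row!r} "
                f"is not in {VALID_TISSUES}"
            )
        if adata.var_names.duplicated().any():
            dup = adata.var_names[adata.var_names.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r}")
        self.adata = adata

    # -- container views ---------------------------------------------------
    @property
    def values(self) -> sp.csr_matrix:
        return self.adata.X

    @property
    def gene_index(self) -> pd.Index:
        return self.adata.var_names

    @property
    def cell_index(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def shape(self) -> tuple[int, int]:
        return self.adata.shape

    def gene_column(self, gene: str) -> np.ndarray:
        """Dense expression vector of one gene over all cells."""
        if gene not in self.adata.var_names:
            raise KeyError(f"gene {gene!r} not in matrix")
        j = self.adata.var_names.get_loc(gene)
        return np.asarray(self.adata.X[:, j].todense()).ravel()

    def normalized(self, mode: str = "cpm_log1p") -> "CellMatrix":
        """Return a copy on the requested expression scale.

        ``cpm_log1p`` is the standard single-cell scale: per-cell library size
        normalized to 10,000 counts, then log1p. ``counts`` returns a copy
        unchanged.
        """
        if mode == "counts":
            return CellMatrix(self.adata.copy())
        if mode != "cpm_log1p":
            raise ValueError(f"unknown normalization {mode!r}")
        import scanpy as sc

        adata = self.adata.copy()
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        return CellMatrix(adata)


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    meta_path: str | Path,
) -> CellMatrix:
    """Load a MatrixMarket cells x genes triplet with its index and metadata files.

    Cells absent from the metadata table are dropped (count logged); a tissue
    value outside {tumor, normal} raises naming the offending row. An empty
    tissue field is kept as missing (such cells are excluded from safety
    features only).
    """
    try:
        X = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
        raise ValueError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
    X = sp.csr_matrix(X, dtype=np.float64)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).str.strip()
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).str.strip()
    if X.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(cells)} cells x {len(genes)} genes"
        )
    if X.size and X.min() < 0:
        raise ValueError(f"negative expression entry in {matrix_path}")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"cell metadata missing columns {sorted(missing_cols)}")
    meta = meta.set_index("cell_id")
    for i, (cid, tissue) in enumerate(meta["tissue"].items()):
        if pd.notna(tissue) and tissue not in VALID_TISSUES:
            raise ValueError(
                f"cell metadata row {i} (cell {cid!r}): tissue {tissue!r} not in {VALID_TISSUES}"
            )

    keep = cells.isin(meta.index)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d cells absent from metadata", n_dropped)
    cells_kept = cells[keep.values].tolist()
    adata = AnnData(
        X=X[np.flatnonzero(keep.values), :],
        obs=meta.loc[cells_kept, ["cell_type", "tissue", "patient"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obs_names = cells_kept
    return CellMatrix(adata)


def write_expression(matrix: CellMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx, genes.tsv, barcodes.tsv, cell_meta.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "barcodes.tsv",
        "meta": out / "cell_meta.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(matrix.values))
    paths["genes"].write_text("\n".join(matrix.gene_index) + "\n")
    paths["cells"].write_text("\n".join(matrix.cell_index) + "\n")
    meta = matrix.cell_meta.reset_index(names="cell_id")
    meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# drug table


@dataclass
class DrugTableResult:
    records: list[DrugRecord]
    n_rejected: int
    rejections: list[tuple[str, str]]  # (drug_id or row label, reason)


def read_drug_table(path: str | Path) -> DrugTableResult:
    """Parse the drug clinical-progress table (TSV or XLSX).

    Expected columns: ``drug``, ``target_a``, ``target_b``,
    ``clinical_progress``. Rows whose stage text cannot be mapped to the
    5-level ordinal, or whose two targets coincide, are rejected and counted.
    """
    from .labeling import parse_stage

    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug", "target_a", "target_b", "clinical_progress"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns {sorted(missing)}")

    records: list[DrugRecord] = []
    rejections: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        drug_id = str(row["drug"]).strip()
        try:
            pair = GenePair(str(row["target_a"]), str(row["target_b"]))
        except ValueError as exc:
            rejections.append((drug_id, f"bad target pair: {exc}"))
            continue
        stage_text = str(row["clinical_progress"]).strip()
        try:
            code = parse_stage(stage_text)
        except ValueError as exc:
            rejections.append((drug_id, str(exc)))
            continue
        records.append(DrugRecord(drug_id, pair, stage_text, code))
    if rejections:
        logger.warning("rejected %d drug-table rows", len(rejections))
    return DrugTableResult(records, len(rejections), rejections)


def write_drug_table(records: Sequence[DrugRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "drug": [r.drug_id for r in records],
            "target_a": [r.pair.gene_a for r in records],
            "target_b": [r.pair.gene_b for r in records],
            "clinical_progress": [r.stage_text for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathway / embedding / gene-list I/O


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT file (name, description, genes per tab-separated line).

    Duplicate genes within one pathway are de-duplicated.
    """
    pathways: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name = fields[0].strip()
        if name in pathways:
            raise ValueError(f"{path}:{lineno}: duplicate pathway id {name!r}")
        genes = {g.strip() for g in fields[2:] if g.strip()}
        if not genes:
            raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
        pathways[name] = genes
    return PathwayDB(pathways, source=str(path))


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    lines = [
        "\t".join([name, db.source or "na", *sorted(genes)])
        for name, genes in sorted(db.pathways.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_embeddings(path: str | Path) -> GeneEmbeddingTable:
    """Read a gene-embedding TSV: gene symbol then n floats per line."""
    vectors: dict[str, np.ndarray] = {}
    dim = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        gene = fields[0].strip()
        vec = np.array([float(v) for v in fields[1:]], dtype=float)
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(
                f"{path}:{lineno}: ragged embedding row for {gene!r} "
                f"(length {vec.size}, expected {dim})"
            )
        vectors[gene] = vec
    if not vectors:
        raise ValueError(f"embedding file {path} is empty")
    return GeneEmbeddingTable(vectors)


def write_embeddings(emb: GeneEmbeddingTable, path: str | Path) -> None:
    lines = [
        "\t".join([gene, *(repr(float(v)) for v in vec)])
        for gene, vec in emb.vectors.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line candidate list; order preserved, must be non-empty."""
    genes = [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]
    if not genes:
        raise ValueError(f"gene list {path} is empty")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------------------
# candidate enumeration


def enumerate_candidates(gene_list: Sequence[str]) -> list[GenePair]:
    """All C(m, 2) unordered pairs of a unique gene list, lexicographic order."""
    genes = [g.strip() for g in gene_list]
    if len(genes) != len(set(genes)):
        seen: set[str] = set()
        dup = next(g for g in genes if g in seen or seen.add(g))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate gene {dup!r} in candidate list")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form candidate pairs")
    return [GenePair(a, b) for a, b in itertools.combinations(sorted(genes), 2)]
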