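"""Core domain types shared by every stage of the pipeline.

The central object is the unordered :class:`GenePair` — the two arms of a
candidate bispecific antibody.  Everything downstream (features, labels,
model rows, reports) is keyed by a canonical pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "GenePair",
    "GeneEmbeddingTable",
    "PathwayDB",
    "DrugRecord",
    "PairLabel",
    "PreferencePair",
    "RunConfig",
]


@dataclass(frozen=True, order=True)
class GenePair:
    """An unordered pair of gene symbols, stored in canonical (sorted) order.

    ``GenePair("B", "A") == GenePair("A", "B")``; the two symbols must differ.
    """

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        a = self.gene_a.strip()
        b = self.gene_b.strip()
        if not a or not b:
            raise ValueError("gene symbols must be non-empty")
        if a == b:
            raise ValueError(f"a target pair needs two distinct genes, got {a!r} twice")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)

    def __iter__(self) -> Iterator[str]:
        yield self.gene_a
        yield self.gene_b

    def __str__(self) -> str:  # "CD274|CTLA4"
        return f"{self.gene_a}|{self.gene_b}"

    @classmethod
    def from_string(cls, text: str, sep: str = "|") -> "GenePair":
        parts = [p for p in text.split(sep) if p.strip()]
        if len(parts) != 2:
            raise ValueError(f"cannot parse gene pair from {text!r}")
        return cls(parts[0], parts[1])


class GeneEmbeddingTable:
    """Pre-trained gene embeddings: gene symbol -> fixed-length real vector.

    All vectors share one dimensionality ``dim`` (whatever the source file
    provides; Gene2Vec-style tables ship 200-d vectors).
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table is empty")
        self.vectors: dict[str, np.ndarray] = {}
        dim = None
        for gene, vec in vectors.items():
            arr = np.asarray(vec, dtype=float).ravel()
            if dim is None:
                dim = arr.size
                if dim < 1:
                    raise ValueError("embedding vectors must have length >= 1")
            elif arr.size != dim:
                raise ValueError(
                    f"inconsistent embedding dimensions: {gene!r} has {arr.size}, expected {dim}"
                )
            self.vectors[gene.strip()] = arr
        self.dim: int = int(dim)

    def __contains__(self, gene: str) -> bool:
        return gene in self.vectors

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.vectors[gene]

    def __len__(self) -> int:
        return len(self.vectors)


class PathwayDB:
    """Named gene sets (pathways), e.g. loaded from a GMT file."""

    def __init__(self, pathways: Mapping[str, set[str]], source: str = ""):
        self.pathways: dict[str, set[str]] = {}
        for name, genes in pathways.items():
            gene_set = {g.strip() for g in genes if g and g.strip()}
            if not gene_set:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            if name in self.pathways:
                raise ValueError(f"duplicate pathway id {name!r}")
            self.pathways[name] = gene_set
        self.source = source

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())


@dataclass(frozen=True)
class DrugRecord:
    """One bispecific drug: its target pair and clinical-progress stage.

    ``stage_code`` follows the 5-level clinical-progress ordinal where 1 is
    most advanced (Approved/NDA/BLA) and 5 least (Discontinued/pending).
    """

    drug_id: str
    pair: GenePair
    stage_text: str
    stage_code: int

    def __post_init__(self) -> None:
        if self.stage_code not in (1, 2, 3, 4, 5):
            raise ValueError(f"stage_code must be 1..5, got {self.stage_code}")


@dataclass(frozen=True)
class PairLabel:
    """Aggregated supervision for one target pair.

    ``best_stage`` is the most advanced (minimum) stage code over all drugs
    sharing the pair; ``binary`` marks approval (stage 1) under the default
    positive-class policy.
    """

    pair: GenePair
    best_stage: int
    binary: int
    n_drugs: int

    def __post_init__(self) -> None:
        if self.best_stage not in (1, 2, 3, 4, 5):
            raise ValueError(f"best_stage must be 1..5, got {self.best_stage}")
        if self.binary not in (0, 1):
            raise ValueError("binary label must be 0 or 1")
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be >= 1")


@dataclass(frozen=True)
class PreferencePair:
    """A ranking preference: ``winner`` is in a more advanced stage than ``loser``."""

    winner: GenePair
    loser: GenePair


@dataclass
class RunConfig:
    """Run-level knobs shared across pipeline stages.

    Parameters
    ----------
    activity_threshold : float
        Expression threshold T for positive/double-positive proportions, on
        the configured normalization scale. 0 means "any nonzero expression".
    top_k_populations : int
        Number of highest-mean-expression cell populations evaluated per gene.
    focus_cell_types : tuple of str
        Cell populations for which per-population ("@cell_type") feature
        variants are always emitted.
    n_bins : int
        Number of equal-frequency bins for language discretization (<= 5).
    cv_folds : int
        Cross-validation folds.
    seed : int
        Master random seed.
    model_kind : str
        Default model configuration name.
    normalization : str
        "cpm_log1p" (library-size to 10k then log1p) or "counts" (raw).
    """

    activity_threshold: float = 0.0
    top_k_populations: int = 2
    focus_cell_types: tuple[str, ...] = (
        "exhausted CD8 T",
        "Treg",
        "macrophage",
        "epithelial",
    )
    n_bins: int = 5
    cv_folds: int = 5
    seed: int = 0
    model_kind: str = "gbtree_pairwise"
    normalization: str = "cpm_log1p"
    missing_sentinel: float = float("nan")

    def __post_init__(self) -> None:
        if self.activity_threshold < 0:
            raise ValueError("activity_threshold must be non-negative")
        if self.top_k_populations < 1:
            raise ValueError("top_k_populations must be positive")
        if not (1 <= self.n_bins <= 5):
            raise ValueError("n_bins must be in 1..5")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.normalization not in ("counts", "cpm_log1p"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
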