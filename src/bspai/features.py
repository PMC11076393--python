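"""Pair features for bispecific-target prioritization.

Five feature groups are computed for an unordered gene pair (x, y) from an
annotated expression matrix, a pathway database and a gene-embedding table:

* **safety** — quasi-harmonic mean ``d_x * d_y / (d_x + d_y)`` of the
  per-gene tumor-minus-normal pseudo-bulk mean differences ``d``; higher
  means more tumor-restricted, hence safer.
* **mechanism** — number of pathways containing both genes.
* **embedding** — Euclidean distance between the genes' embedding vectors
  (small distance = similar genes).
* **activity** — positive proportion ``P_gene`` (fraction of a population's
  cells with expression strictly above a threshold T) and double-positive
  proportion ``P_gene1,gene2`` (both above T in the same cell), evaluated in
  each gene's top-k highest-mean populations and in a fixed list of focus
  cell types of the tumor microenvironment.
* **correlation** — Pearson r between the two genes' per-cell expression.

All single-population aggregates use ``P_gene = max`` over the gene's top-k
populations, which guarantees ``double_ratio_max <= single_ratio_max``.

:class:`PairFeaturizer` is the batch interface: ``fit`` takes the resources
and precomputes population statistics once; ``transform`` maps a list of
pairs to a named feature table.  The module-level functions are the
single-pair reference operations.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core_io import CellMatrix
from .types import GenePair, GeneEmbeddingTable, PathwayDB, RunConfig

logger = logging.getLogger("bspai")

DEGENERATE_EPS = 1e-12

#: ablation/reporting feature groups, in cumulative-inclusion order
FEATURE_GROUP_ORDER = (
    "double_positive",
    "safety",
    "mechanism",
    "embedding",
    "single_cell_expression",
    "grouped_cell_type",
)


def feature_groups(feature_names: Iterable[str]) -> dict[str, list[str]]:
    """Partition feature names into the six named groups.

    Per-population variants carry an ``@cell_type`` suffix and form the
    ``grouped_cell_type`` group; everything else is pooled.
    """
    groups: dict[str, list[str]] = {g: [] for g in FEATURE_GROUP_ORDER}
    for name in feature_names:
        if "@" in name:
            groups["grouped_cell_type"].append(name)
        elif name == "double_ratio_max":
            groups["double_positive"].append(name)
        elif name == "safety_score":
            groups["safety"].append(name)
        elif name == "cooccurrence_count":
            groups["mechanism"].append(name)
        elif name == "embedding_distance":
            groups["embedding"].append(name)
        else:
            groups["single_cell_expression"].append(name)
    return groups


# ---------------------------------------------------------------------------
# single-pair reference operations


def pseudo_bulk_mean(matrix: CellMatrix, gene: str, tissue: str) -> float:
    """Mean expression of ``gene`` over all cells of one tissue compartment.

    Operates on the matrix's current expression scale (normalize first via
    :meth:`CellMatrix.normalized` if desired).
    """
    mask = (matrix.cell_meta["tissue"] == tissue).to_numpy()
    if not mask.any():
        raise ValueError(
            f"no cells with tissue {tissue!r}; skip the safety feature for this matrix"
        )
    return float(matrix.gene_column(gene)[mask].mean())


def compute_safety_score(matrix: CellMatrix, pair: GenePair) -> float:
    """Quasi-harmonic safety score ``d_x * d_y / (d_x + d_y)``.

    ``d = expr_tumor - expr_normal`` per gene.  Degenerate cases (sum near
    zero, or opposite-sign differences where the quasi-harmonic mean is not
    monotone) return 0 with a warning; higher = safer, symmetric in the pair.
    """
    d_x = pseudo_bulk_mean(matrix, pair.gene_a, "tumor") - pseudo_bulk_mean(
        matrix, pair.gene_a, "normal"
    )
    d_y = pseudo_bulk_mean(matrix, pair.gene_b, "tumor") - pseudo_bulk_mean(
        matrix, pair.gene_b, "normal"
    )
    return safety_from_differences(d_x, d_y)


def safety_from_differences(d_x: float, d_y: float, warn: bool = True) -> float:
    """The safety combination rule on precomputed per-gene differences.

    Degenerate inputs (near-zero denominator, or opposite-sign differences
    where the quasi-harmonic mean is not monotone) yield 0.
    """
    if abs(d_x + d_y) < DEGENERATE_EPS:
        if warn:
            logger.warning("safety score degenerate denominator (d_x=%g, d_y=%g)", d_x, d_y)
        return 0.0
    if d_x * d_y < 0:
        if warn:
            logger.warning("safety score opposite-sign differences (d_x=%g, d_y=%g)", d_x, d_y)
        return 0.0
    return float(d_x * d_y / (d_x + d_y))


def compute_cooccurrence(pair: GenePair, db: PathwayDB) -> int:
    """Number of pathways containing both genes of the pair."""
    if len(db) == 0:
        raise ValueError("pathway database is empty")
    return sum(1 for _, genes in db if pair.gene_a in genes and pair.gene_b in genes)


def compute_embedding_distance(pair: GenePair, emb: GeneEmbeddingTable) -> float:
    """Euclidean distance ``sqrt(sum_i (x_i - y_i)^2)`` between gene vectors."""
    for gene in pair:
        if gene not in emb:
            raise KeyError(f"gene {gene!r} absent from embedding table")
    diff = emb[pair.gene_a] - emb[pair.gene_b]
    return float(np.sqrt(np.dot(diff, diff)))


def _population_mask(matrix: CellMatrix, cell_type: str) -> np.ndarray:
    mask = (matrix.cell_meta["cell_type"] == cell_type).to_numpy()
    if not mask.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    return mask


def positive_proportion(matrix: CellMatrix, gene: str, cell_type: str, threshold: float) -> float:
    """Fraction of a population's cells with expression strictly above T."""
    mask = _population_mask(matrix, cell_type)
    return float((matrix.gene_column(gene)[mask] > threshold).mean())


def double_positive_proportion(
    matrix: CellMatrix, pair: GenePair, cell_type: str, threshold: float
) -> float:
    """Fraction of a population's cells where both genes exceed T."""
    mask = _population_mask(matrix, cell_type)
    a = matrix.gene_column(pair.gene_a)[mask] > threshold
    b = matrix.gene_column(pair.gene_b)[mask] > threshold
    return float((a & b).mean())


def select_top_populations(matrix: CellMatrix, gene: str, k: int) -> list[str]:
    """The k cell types with the highest mean expression of ``gene``.

    Ties break lexicographically by cell-type name; if fewer than k
    populations exist, all are returned with a warning.
    """
    col = matrix.gene_column(gene)
    cell_types = matrix.cell_meta["cell_type"]
    means = {
        ct: float(col[(cell_types == ct).to_numpy()].mean()) for ct in sorted(cell_types.unique())
    }
    if len(means) < k:
        logger.warning("only %d populations available, requested top %d", len(means), k)
        k = len(means)
    ranked = sorted(means, key=lambda ct: (-means[ct], ct))
    return ranked[:k]


def compute_pearson(matrix: CellMatrix, pair: GenePair, scope: str | None = None) -> float:
    """Sample Pearson correlation of the two genes' per-cell expression.

    ``scope`` is None (all cells pooled) or one cell-type name.  A gene with
    zero variance in scope yields 0 with a warning.
    """
    if scope is None:
        mask = np.ones(matrix.shape[0], dtype=bool)
    else:
        mask = _population_mask(matrix, scope)
    if mask.sum() < 3:
        raise ValueError("Pearson correlation needs at least 3 cells in scope")
    x = matrix.gene_column(pair.gene_a)[mask]
    y = matrix.gene_column(pair.gene_b)[mask]
    return _pearson(x, y)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.dot(xc, xc)) * np.sqrt(np.dot(yc, yc))
    if denom < DEGENERATE_EPS:
        logger.warning("zero variance in Pearson scope; correlation recorded as 0")
        return 0.0
    return float(np.dot(xc, yc) / denom)


def compute_activity_features(
    matrix: CellMatrix, pair: GenePair, cfg: RunConfig
) -> dict[str, float]:
    """Positive/double-positive proportions over top-k and focus populations.

    Pooled aggregates: ``single_ratio_sum/min/max`` from each gene's
    ``P_gene`` (max proportion over its top-k populations) and
    ``double_ratio_max`` over the union of both genes' top-k populations.
    Per-population variants are emitted for every focus cell type present.
    """
    T = cfg.activity_threshold
    top_a = select_top_populations(matrix, pair.gene_a, cfg.top_k_populations)
    top_b = select_top_populations(matrix, pair.gene_b, cfg.top_k_populations)
    p_a = max(positive_proportion(matrix, pair.gene_a, ct, T) for ct in top_a)
    p_b = max(positive_proportion(matrix, pair.gene_b, ct, T) for ct in top_b)
    evaluated = sorted(set(top_a) | set(top_b))
    double = {ct: double_positive_proportion(matrix, pair, ct, T) for ct in evaluated}
    feats = {
        "single_ratio_sum": p_a + p_b,
        "single_ratio_min": min(p_a, p_b),
        "single_ratio_max": max(p_a, p_b),
        "double_ratio_max": max(double.values()),
    }
    present = set(matrix.cell_meta["cell_type"].unique())
    for ct in cfg.focus_cell_types:
        if ct not in present:
            continue
        pa = positive_proportion(matrix, pair.gene_a, ct, T)
        pb = positive_proportion(matrix, pair.gene_b, ct, T)
        feats[f"single_ratio_sum@{ct}"] = pa + pb
        feats[f"single_ratio_min@{ct}"] = min(pa, pb)
        feats[f"single_ratio_max@{ct}"] = max(pa, pb)
        feats[f"double_ratio@{ct}"] = double_positive_proportion(matrix, pair, ct, T)
    return feats


def build_feature_vector(
    pair: GenePair,
    matrix: CellMatrix,
    db: PathwayDB,
    emb: GeneEmbeddingTable,
    cfg: RunConfig | None = None,
) -> pd.Series:
    """Full named feature vector for a single pair (convenience wrapper)."""
    cfg = cfg or RunConfig()
    featurizer = PairFeaturizer(
        activity_threshold=cfg.activity_threshold,
        top_k_populations=cfg.top_k_populations,
        focus_cell_types=cfg.focus_cell_types,
        normalization=cfg.normalization,
    )
    featurizer.fit(matrix, pathways=db, embeddings=emb)
    return featurizer.transform([pair]).iloc[0]


# ---------------------------------------------------------------------------
# batch featurizer


class PairFeaturizer(BaseEstimator, TransformerMixin):
    """Transform gene pairs into named feature rows.

    Parameters
    ----------
    activity_threshold : float, default 0.0
        Expression threshold T (on the configured scale) above which a cell
        counts as positive for a gene.
    top_k_populations : int, default 2
        Populations with the highest mean expression evaluated per gene.
    focus_cell_types : tuple of str
        Cell types for which ``@cell_type`` feature variants are emitted
        (those absent from the matrix are silently skipped, but the emitted
        name list is identical for every pair in one run).
    normalization : {"cpm_log1p", "counts"}, default "cpm_log1p"
        Expression scale applied once at fit time.
    pearson_per_population : bool, default True
        Also emit ``pearson_r@cell_type`` for focus populations.

    Attributes
    ----------
    feature_names_ : list of str
        Stable, documented column order of the transform output.
    """

    def __init__(
        self,
        activity_threshold: float = 0.0,
        top_k_populations: int = 2,
        focus_cell_types: Sequence[str] = RunConfig().focus_cell_types,
        normalization: str = "cpm_log1p",
        pearson_per_population: bool = True,
    ):
        self.activity_threshold = activity_threshold
        self.top_k_populations = top_k_populations
        self.focus_cell_types = tuple(focus_cell_types)
        self.normalization = normalization
        self.pearson_per_population = pearson_per_population

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        X: CellMatrix,
        y=None,
        *,
        pathways: PathwayDB | None = None,
        embeddings: GeneEmbeddingTable | None = None,
    ) -> "PairFeaturizer":
        """Precompute population statistics from the expression matrix.

        ``pathways`` and ``embeddings`` are optional resources; features that
        depend on a missing resource are emitted as NaN sentinels.
        """
        matrix = X.normalized(self.normalization)
        self.pathways_ = pathways
        self.embeddings_ = embeddings
        self.genes_ = list(matrix.gene_index)
        self.gene_pos_ = {g: i for i, g in enumerate(self.genes_)}

        dense = np.asarray(matrix.values.todense(), dtype=np.float64)
        self._X = dense
        self._B = dense > self.activity_threshold

        cell_types = matrix.cell_meta["cell_type"].to_numpy()
        self.populations_ = sorted(pd.unique(cell_types))
        self._pop_masks = {ct: cell_types == ct for ct in self.populations_}
        self._pop_mean = {ct: dense[m].mean(axis=0) for ct, m in self._pop_masks.items()}
        self._pop_prop = {
            ct: self._B[m].mean(axis=0) for ct, m in self._pop_masks.items()
        }
        # per-population joint-positive counts, genes x genes
        self._pop_double = {}
        for ct, m in self._pop_masks.items():
            Bm = self._B[m].astype(np.float64)
            self._pop_double[ct] = (Bm.T @ Bm) / m.sum()

        # top-k populations per gene: highest mean, ties lexicographic
        mean_table = np.vstack([self._pop_mean[ct] for ct in self.populations_])
        k = min(self.top_k_populations, len(self.populations_))
        if k < self.top_k_populations:
            logger.warning(
                "only %d populations available, requested top %d",
                len(self.populations_),
                self.top_k_populations,
            )
        self._top_pops = []
        for j in range(len(self.genes_)):
            order = sorted(
                range(len(self.populations_)),
                key=lambda i: (-mean_table[i, j], self.populations_[i]),
            )
            self._top_pops.append([self.populations_[i] for i in order[:k]])

        # tumor/normal pseudo-bulk differences (cells with missing tissue excluded)
        tissue = matrix.cell_meta["tissue"]
        tmask = (tissue == "tumor").to_numpy()
        nmask = (tissue == "normal").to_numpy()
        if tmask.any() and nmask.any():
            self.tissue_diff_ = dense[tmask].mean(axis=0) - dense[nmask].mean(axis=0)
        else:
            logger.warning("tumor or normal compartment absent; safety features set to NaN")
            self.tissue_diff_ = None

        # Pearson building blocks (pooled and per focus population)
        self._corr_stats = {}
        scopes = [None]
        if self.pearson_per_population:
            scopes += [ct for ct in self.focus_cell_types if ct in self._pop_masks]
        for scope in scopes:
            sub = dense if scope is None else dense[self._pop_masks[scope]]
            centered = sub - sub.mean(axis=0, keepdims=True)
            norms = np.sqrt((centered**2).sum(axis=0))
            self._corr_stats[scope] = (centered, norms)

        self.focus_present_ = [ct for ct in self.focus_cell_types if ct in self._pop_masks]
        self.feature_names_ = self._make_feature_names()
        return self

    def _make_feature_names(self) -> list[str]:
        names = [
            "safety_score",
            "cooccurrence_count",
            "embedding_distance",
            "pearson_r",
            "single_ratio_sum",
            "single_ratio_min",
            "single_ratio_max",
            "double_ratio_max",
        ]
        for ct in self.focus_present_:
            names += [
                f"single_ratio_sum@{ct}",
                f"single_ratio_min@{ct}",
                f"single_ratio_max@{ct}",
                f"double_ratio@{ct}",
            ]
            if self.pearson_per_population:
                names.append(f"pearson_r@{ct}")
        return names

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)

    # -- transform ---------------------------------------------------------
    def _pearson_from_stats(self, scope, ia: int, ib: int) -> float:
        centered, norms = self._corr_stats[scope]
        denom = norms[ia] * norms[ib]
        if denom < DEGENERATE_EPS:
            return 0.0
        return float(np.dot(centered[:, ia], centered[:, ib]) / denom)

    def _row(self, pair: GenePair) -> dict[str, float]:
        row: dict[str, float] = dict.fromkeys(self.feature_names_, np.nan)
        ia = self.gene_pos_.get(pair.gene_a)
        ib = self.gene_pos_.get(pair.gene_b)

        if self.pathways_ is not None and len(self.pathways_) > 0:
            row["cooccurrence_count"] = float(compute_cooccurrence(pair, self.pathways_))
        if self.embeddings_ is not None and pair.gene_a in self.embeddings_ and pair.gene_b in self.embeddings_:
            row["embedding_distance"] = compute_embedding_distance(pair, self.embeddings_)

        if ia is None or ib is None:
            return row  # expression features stay at the NaN sentinel

        if self.tissue_diff_ is not None:
            d_x = float(self.tissue_diff_[ia])
            d_y = float(self.tissue_diff_[ib])
            row["safety_score"] = safety_from_differences(d_x, d_y, warn=False)
            if abs(d_x + d_y) < DEGENERATE_EPS or d_x * d_y < 0:
                self._n_degenerate_safety += 1
        row["pearson_r"] = self._pearson_from_stats(None, ia, ib)

        p_a = max(self._pop_prop[ct][ia] for ct in self._top_pops[ia])
        p_b = max(self._pop_prop[ct][ib] for ct in self._top_pops[ib])
        row["single_ratio_sum"] = float(p_a + p_b)
        row["single_ratio_min"] = float(min(p_a, p_b))
        row["single_ratio_max"] = float(max(p_a, p_b))
        evaluated = set(self._top_pops[ia]) | set(self._top_pops[ib])
        row["double_ratio_max"] = float(
            max(self._pop_double[ct][ia, ib] for ct in evaluated)
        )

        for ct in self.focus_present_:
            pa = float(self._pop_prop[ct][ia])
            pb = float(self._pop_prop[ct][ib])
            row[f"single_ratio_sum@{ct}"] = pa + pb
            row[f"single_ratio_min@{ct}"] = min(pa, pb)
            row[f"single_ratio_max@{ct}"] = max(pa, pb)
            row[f"double_ratio@{ct}"] = float(self._pop_double[ct][ia, ib])
            if self.pearson_per_population:
                row[f"pearson_r@{ct}"] = self._pearson_from_stats(ct, ia, ib)
        return row

    def transform(self, pairs: Iterable[GenePair]) -> pd.DataFrame:
        """Feature table with one row per pair, indexed by the canonical pair string."""
        pairs = list(pairs)
        self._n_degenerate_safety = 0
        rows = [self._row(p) for p in pairs]
        if self._n_degenerate_safety:
            logger.warning(
                "safety score degenerate (zero/opposite-sign differences) for %d of %d pairs",
                self._n_degenerate_safety,
                len(pairs),
            )
        df = pd.DataFrame(rows, index=[str(p) for p in pairs], columns=self.feature_names_)
        df.index.name = "pair"
        return df


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="pair")
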