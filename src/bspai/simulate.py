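"""Synthetic study generator: all five input files with planted signal.

The generator emulates the statistical structure the feature engine assumes,
planting signal at the level where each biological quantity lives:

* **gene level** — a tumor-specificity boost ``t_g`` (tumor cells express the
  gene ``1 + safe_scale * t_g`` times higher), and a home-population activity
  ``a_g`` (the gene's home cell type expresses it ``1 + coexpr_scale * a_g``
  times higher), so that pairs sharing genes stay mutually consistent;
* **pair level** — labeled pairs are pulled together in embedding space with
  strength ``emb_scale`` and co-assigned to up to ``max_shared_pathways``
  shared pathways.

The latent druggability of a labeled pair is the standardized sum of the
rank-normalized planted components: quasi-harmonic tumor specificity of its
two genes, realized embedding proximity, realized shared-pathway count, and
same-home co-activity.  Components whose scale is 0 carry no signal and are
excluded.  Clinical stages follow latent quintiles (most druggable = stage 1,
approved) and are flipped to a random stage with probability ``stage_noise``;
stage texts come verbatim from the 5-level clinical-progress vocabulary.

Counts are negative binomial with dropout.  Every output is a pure function
of :class:`SimConfig` including its seed; ground truth is always returned
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .core_io import (
    CellMatrix,
    write_drug_table,
    write_embeddings,
    write_expression,
    write_gene_list,
    write_gmt,
)
from .labeling import STAGE_VOCABULARY
from .types import DrugRecord, GenePair, GeneEmbeddingTable, PathwayDB

DEFAULT_CELL_TYPES = {
    "exhausted CD8 T": 0.15,
    "Treg": 0.10,
    "macrophage": 0.15,
    "epithelial": 0.30,
    "fibroblast": 0.15,
    "B cell": 0.15,
}

HOME_POPULATIONS = ("exhausted CD8 T", "Treg", "macrophage", "epithelial")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Effect scales multiply planted intensities drawn uniformly in [0, 1];
    setting a scale (or ``max_shared_pathways``) to 0 removes that signal
    and its latent component entirely.
    """

    n_cells: int = 2000
    n_genes: int = 223
    cell_types: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    tumor_fraction: float = 0.6
    n_patients: int = 8
    n_labeled_pairs: int = 600
    coexpr_scale: float = 3.0  # home-population activity boost strength
    safe_scale: float = 2.0  # tumor-specific mean boost strength
    emb_scale: float = 4.0  # embedding pull; weight delta/(1+delta)
    max_shared_pathways: int = 4
    nb_dispersion: float = 0.5
    dropout: float = 0.1
    n_drugs: int = 791
    stage_noise: float = 0.1
    embedding_dim: int = 200
    n_pathways: int = 300
    pathway_gene_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cell_types.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell-type proportions must sum to 1, got {total}")
        if not (0.0 <= self.stage_noise <= 1.0):
            raise ValueError("stage_noise must be in [0, 1]")
        for name in ("coexpr_scale", "safe_scale", "emb_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_drugs < self.n_labeled_pairs:
            raise ValueError("need at least one drug per labeled pair")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class PlantedTruth:
    """Gene- and pair-level planted structure (pure function of the config)."""

    genes: list[str]
    tumor_boost: np.ndarray  # t_g in [0, 1]
    activity: np.ndarray  # a_g in [0, 1]
    home_population: list[str]  # home cell type per gene
    pairs: list[GenePair]  # labeled pairs, canonical order
    emb_pull: np.ndarray  # u in [0, 1] per pair; pull weight = d/(1+d), d = emb_scale*u
    shared_pathways: np.ndarray  # planted co-assignments per pair


def plant_effects(cfg: SimConfig) -> PlantedTruth:
    """Draw the gene-level effects and the labeled pair list (pure in cfg.seed)."""
    rng = np.random.default_rng([cfg.seed, 101])
    genes = cfg.gene_names()
    max_pairs = cfg.n_genes * (cfg.n_genes - 1) // 2
    if cfg.n_labeled_pairs > max_pairs:
        raise ValueError(
            f"cannot draw {cfg.n_labeled_pairs} distinct pairs from {cfg.n_genes} genes"
        )
    tumor_boost = rng.uniform(0.0, 1.0, cfg.n_genes)
    activity = rng.uniform(0.0, 1.0, cfg.n_genes)
    home = [HOME_POPULATIONS[k] for k in rng.integers(0, len(HOME_POPULATIONS), cfg.n_genes)]

    chosen: set[tuple[int, int]] = set()
    while len(chosen) < cfg.n_labeled_pairs:
        i, j = rng.integers(0, cfg.n_genes, size=2)
        if i != j:
            chosen.add((min(i, j), max(i, j)))
    pairs = [GenePair(genes[i], genes[j]) for i, j in sorted(chosen)]
    emb_pull = rng.uniform(0.0, 1.0, len(pairs))
    shared = np.round(rng.uniform(0.0, 1.0, len(pairs)) * cfg.max_shared_pathways).astype(int)
    return PlantedTruth(
        genes=genes,
        tumor_boost=tumor_boost,
        activity=activity,
        home_population=home,
        pairs=pairs,
        emb_pull=emb_pull,
        shared_pathways=shared,
    )


def simulate_cell_matrix(cfg: SimConfig) -> tuple[CellMatrix, pd.DataFrame]:
    """Negative-binomial counts with cell-type structure and planted boosts.

    Tumor cells express gene g ``1 + safe_scale * t_g`` times higher; cells
    of g's home population express it ``1 + coexpr_scale * a_g`` times
    higher.  Genes sharing a home population are therefore co-active there,
    producing co-expression blocks and double-positive enrichment.
    """
    rng = np.random.default_rng([cfg.seed, 202])
    truth = plant_effects(cfg)
    type_names = sorted(cfg.cell_types)
    probs = np.array([cfg.cell_types[t] for t in type_names])
    cell_type = rng.choice(type_names, size=cfg.n_cells, p=probs)
    tissue = np.where(rng.random(cfg.n_cells) < cfg.tumor_fraction, "tumor", "normal")
    patient = np.array([f"P{k:02d}" for k in rng.integers(0, cfg.n_patients, cfg.n_cells)])

    base = rng.lognormal(mean=-0.7, sigma=1.0, size=cfg.n_genes)
    type_factor = {t: rng.lognormal(0.0, 0.4, size=cfg.n_genes) for t in type_names}
    mean = np.empty((cfg.n_cells, cfg.n_genes))
    for t in type_names:
        mask = cell_type == t
        mean[mask] = base * type_factor[t]
        # home-population activity boost for genes homed in t
        homed = np.array([h == t for h in truth.home_population])
        if homed.any():
            mean[np.ix_(mask, homed)] *= 1.0 + cfg.coexpr_scale * truth.activity[homed]
    mean[tissue == "tumor"] *= 1.0 + cfg.safe_scale * truth.tumor_boost

    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mean * cfg.nb_dispersion)
    counts = rng.poisson(lam).astype(np.float64)
    if cfg.dropout > 0:
        counts *= rng.random(counts.shape) >= cfg.dropout

    obs = pd.DataFrame(
        {"cell_type": cell_type, "tissue": tissue, "patient": patient},
        index=[f"C{i:05d}" for i in range(cfg.n_cells)],
    )
    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(truth.genes, name="gene")),
    )
    gene_truth = pd.DataFrame(
        {
            "tumor_boost": truth.tumor_boost,
            "activity": truth.activity,
            "home_population": truth.home_population,
        },
        index=pd.Index(truth.genes, name="gene"),
    )
    return CellMatrix(adata), gene_truth


def simulate_embeddings(cfg: SimConfig) -> GeneEmbeddingTable:
    """Isotropic Gaussian gene vectors; labeled pairs pulled together.

    The pull weight is ``delta / (1 + delta)`` with ``delta = emb_scale * u``
    for a per-pair intensity u in [0, 1]: as emb_scale grows the planted
    pairs' distances shrink toward 0.
    """
    rng = np.random.default_rng([cfg.seed, 303])
    truth = plant_effects(cfg)
    vecs = {g: rng.standard_normal(cfg.embedding_dim) for g in truth.genes}
    for p, u in zip(truth.pairs, truth.emb_pull):
        delta = cfg.emb_scale * u
        w = delta / (1.0 + delta)
        vecs[p.gene_b] = (1.0 - w) * vecs[p.gene_b] + w * vecs[p.gene_a]
    return GeneEmbeddingTable(vecs)


def simulate_pathways(cfg: SimConfig) -> PathwayDB:
    """Bernoulli background membership; labeled pairs co-assigned to shared pathways."""
    rng = np.random.default_rng([cfg.seed, 404])
    truth = plant_effects(cfg)
    genes = np.array(truth.genes)
    pathways: dict[str, set[str]] = {}
    for k in range(cfg.n_pathways):
        members = set(genes[rng.random(cfg.n_genes) < cfg.pathway_gene_rate])
        if not members:
            members = {genes[int(rng.integers(0, cfg.n_genes))]}
        pathways[f"PW{k:04d}"] = members
    names = list(pathways)
    for p, k_shared in zip(truth.pairs, truth.shared_pathways):
        if k_shared == 0:
            continue
        chosen = rng.choice(len(names), size=int(k_shared), replace=False)
        for k in chosen:
            pathways[names[k]] |= {p.gene_a, p.gene_b}
    return PathwayDB(pathways, source="synthetic")


def _rank_normalize(values: np.ndarray) -> np.ndarray:
    """Average ranks mapped to [0, 1] (ties share their mean rank)."""
    order = pd.Series(values).rank(method="average").to_numpy() - 1.0
    if len(values) == 1:
        return np.zeros(1)
    return order / (len(values) - 1)


def compute_pair_latents(
    cfg: SimConfig,
    embeddings: GeneEmbeddingTable | None = None,
    pathways: PathwayDB | None = None,
) -> pd.DataFrame:
    """Per-pair planted components and the standardized latent druggability.

    Components (each rank-normalized over the labeled pairs, included only
    when its scale is nonzero):

    * ``c_safe`` — quasi-harmonic mean of the two genes' tumor boosts;
    * ``c_emb`` — negative realized embedding distance;
    * ``c_pathway`` — realized shared-pathway count;
    * ``c_coexpr`` — min activity of the two genes when they share a home
      population, else 0.
    """
    truth = plant_effects(cfg)
    if embeddings is None:
        embeddings = simulate_embeddings(cfg)
    if pathways is None:
        pathways = simulate_pathways(cfg)
    pos = {g: i for i, g in enumerate(truth.genes)}

    comp: dict[str, np.ndarray] = {}
    t = truth.tumor_boost
    safe = np.array(
        [
            2.0 * t[pos[p.gene_a]] * t[pos[p.gene_b]] / (t[pos[p.gene_a]] + t[pos[p.gene_b]])
            for p in truth.pairs
        ]
    )
    comp["c_safe"] = safe
    comp["c_emb"] = np.array(
        [-float(np.linalg.norm(embeddings[p.gene_a] - embeddings[p.gene_b])) for p in truth.pairs]
    )
    comp["c_pathway"] = np.array(
        [
            sum(1 for _, gs in pathways if p.gene_a in gs and p.gene_b in gs)
            for p in truth.pairs
        ],
        dtype=float,
    )
    a = truth.activity
    home = truth.home_population
    comp["c_coexpr"] = np.array(
        [
            min(a[pos[p.gene_a]], a[pos[p.gene_b]])
            if home[pos[p.gene_a]] == home[pos[p.gene_b]]
            else 0.0
            for p in truth.pairs
        ]
    )

    active = {
        "c_safe": cfg.safe_scale > 0,
        "c_emb": cfg.emb_scale > 0,
        "c_pathway": cfg.max_shared_pathways > 0,
        "c_coexpr": cfg.coexpr_scale > 0,
    }
    total = np.zeros(len(truth.pairs))
    normed = {}
    for name, values in comp.items():
        normed[name + "_rank"] = _rank_normalize(values)
        if active[name]:
            total = total + normed[name + "_rank"]
    if total.std() > 0:
        latent = (total - total.mean()) / total.std()
    else:
        latent = np.zeros_like(total)

    df = pd.DataFrame(
        {"pair": [str(p) for p in truth.pairs], **comp, **normed, "latent": latent}
    ).set_index("pair")
    return df


def simulate_drug_table(
    cfg: SimConfig, feature_latents: pd.DataFrame | None = None
) -> list[DrugRecord]:
    """Drug records whose stages follow latent-druggability quintiles plus noise."""
    rng = np.random.default_rng([cfg.seed, 505])
    latents = compute_pair_latents(cfg) if feature_latents is None else feature_latents
    pairs = [GenePair.from_string(p) for p in latents.index]
    latent = latents["latent"].to_numpy()
    n = len(pairs)
    # most druggable pair -> stage 1 (approved); quintiles over the latent order
    order = np.argsort(-latent, kind="stable")
    stage = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        stage[idx] = min(5, 1 + (5 * rank) // n)
    flip = rng.random(n) < cfg.stage_noise
    stage[flip] = rng.integers(1, 6, size=int(flip.sum()))

    pair_of_drug = list(range(n)) + list(rng.integers(0, n, size=cfg.n_drugs - n))
    return [
        DrugRecord(
            drug_id=f"BSD{d:04d}",
            pair=pairs[k],
            stage_text=STAGE_VOCABULARY[int(stage[k])],
            stage_code=int(stage[k]),
        )
        for d, k in enumerate(pair_of_drug)
    ]


@dataclass
class SyntheticStudy:
    """All five generated inputs plus ground truth."""

    matrix: CellMatrix
    embeddings: GeneEmbeddingTable
    pathways: PathwayDB
    drug_records: list[DrugRecord]
    gene_list: list[str]
    pair_truth: pd.DataFrame  # per labeled pair: components + latent
    gene_truth: pd.DataFrame  # per gene: tumor_boost, activity, home_population
    config: SimConfig

    @property
    def labeled_pairs(self) -> list[GenePair]:
        return [GenePair.from_string(p) for p in self.pair_truth.index]


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate the full synthetic study (deterministic in cfg)."""
    matrix, gene_truth = simulate_cell_matrix(cfg)
    embeddings = simulate_embeddings(cfg)
    pathways = simulate_pathways(cfg)
    latents = compute_pair_latents(cfg, embeddings, pathways)
    records = simulate_drug_table(cfg, latents)
    return SyntheticStudy(
        matrix=matrix,
        embeddings=embeddings,
        pathways=pathways,
        drug_records=records,
        gene_list=cfg.gene_names(),
        pair_truth=latents,
        gene_truth=gene_truth,
        config=cfg,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the five input files in exactly the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_expression(study.matrix, out)
    write_embeddings(study.embeddings, out / "embeddings.tsv")
    write_gmt(study.pathways, out / "pathways.gmt")
    write_drug_table(study.drug_records, out / "drug_table.tsv")
    write_gene_list(study.gene_list, out / "gene_list.txt")
    study.pair_truth.to_csv(out / "ground_truth_pairs.tsv", sep="\t")
    study.gene_truth.to_csv(out / "ground_truth_genes.tsv", sep="\t")
    paths.update(
        {
            "embeddings": out / "embeddings.tsv",
            "pathways": out / "pathways.gmt",
            "drugs": out / "drug_table.tsv",
            "genes_list": out / "gene_list.txt",
            "pair_truth": out / "ground_truth_pairs.tsv",
            "gene_truth": out / "ground_truth_genes.tsv",
        }
    )
    return paths
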