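# bspai

Prioritization of **bispecific-antibody (BsAb) target pairs** from annotated
single-cell RNA-seq data, using pairwise learning-to-rank supervised by
ordinal clinical-stage labels, plus natural-language analysis reports built
by equal-frequency feature discretization.

## The problem

A bispecific antibody binds two antigens at once. Choosing which two
membrane proteins to pair is a central and expensive decision in BsAb
development: the pair should be co-active in the right tumor-microenvironment
cell populations, tumor-restricted enough to be safe, and mechanistically
synergistic. `bspai` scores every candidate pair (x, y) from a curated
membrane-protein list by combining five groups of biologically motivated
features with a ranking model trained on the clinical progress of known
bispecific drugs.

## Features

For a pair (x, y), given a cells × genes expression matrix with cell-type,
tissue (tumor/normal) and patient annotations, a pathway database (GMT) and
a Gene2Vec-style gene-embedding table:

- **Safety** — per-gene pseudo-bulk difference d = expr_tumor − expr_normal,
  combined as the quasi-harmonic mean
  `score_safe = d_x · d_y / (d_x + d_y)` (higher = more tumor-restricted =
  safer).
- **Mechanism** — the number of pathways containing both genes.
- **Gene embedding** — Euclidean distance
  `d(x, y) = sqrt(Σᵢ (xᵢ − yᵢ)²)` between embedding vectors (small =
  similar genes).
- **Target activity** — the positive proportion
  `P_gene = Σᵢ I(expr_gene,i > T) / N` and the double-positive proportion
  `P_gene1,gene2 = Σᵢ I(expr_gene1,i > T)·I(expr_gene2,i > T) / N`,
  evaluated in each gene's top-k highest-expressing populations and in
  fixed tumor-microenvironment focus populations (exhausted CD8 T cells,
  Tregs, macrophages, epithelial cells).
- **Expression correlation** — Pearson r of the two genes across single
  cells.

## Supervision and models

Drugs carry a 5-level ordinal clinical-progress code (1 = Approved/NDA/BLA,
2 = Phase 3 or 2/3, 3 = Phase 1 or 2, 4 = Preclinical/IND, 5 =
Discontinued/pending). Each pair inherits the most advanced stage among its
drugs; the ordinal stages induce preference pairs (a more advanced pair
should outscore a less advanced one), which a gradient-boosted-tree ranker
(`XGBRanker`, rank:pairwise) optimizes directly — a better use of scarce
approvals than pointwise classification. Six pointwise configurations
(logistic regression, decision tree, random forest, gradient boosting, a
fully connected neural network, pointwise XGBoost) are benchmarked alongside
it with fivefold cross-validated AUC against the binary "approved" label.
Split-frequency importances, a cumulative feature-group ablation protocol
and candidate ranking round out the bench. Discretizing the six headline
features into up to five equal-frequency bins with ordered natural-language
labels ("Very similar" … "Very dissimilar") yields a deterministic,
retrieval-augmented prompt and an offline analysis report; a pluggable LLM
client can turn the same prompt into free text.

Because the real inputs (four tumor scRNA-seq cohorts and a curated
791-drug clinical-progress table) are external, the package ships a
first-class synthetic generator (`bspai.simulate`) that emits all five input
files with planted, parameterized signal and full ground truth.

## Worked example

```python
from bspai import (
    PairFeaturizer, SimConfig, simulate_study, aggregate_pair_labels,
    build_dataset, crossvalidate, train, rank_candidates,
)

study = simulate_study(SimConfig(seed=42))          # 223 genes, 600 labeled pairs
featurizer = PairFeaturizer().fit(
    study.matrix, pathways=study.pathways, embeddings=study.embeddings
)
X = featurizer.transform(study.labeled_pairs)
labels = aggregate_pair_labels(study.drug_records)  # 791 drugs -> 600 pair labels
dataset = build_dataset(labels, X, cv_folds=5, seed=42)

cv = crossvalidate("gbtree_pairwise", dataset)
print("per-fold AUC:", [round(a, 3) for a in cv.per_fold_auc])
print(f"mean CV AUC: {cv.mean_auc:.4f}")

model = train("gbtree_pairwise", dataset)
print(rank_candidates(model, X).head(3).to_string(index=False))
```

prints

```
per-fold AUC: [0.856, 0.907, 0.827, 0.916, 0.868]
mean CV AUC: 0.8746
       pair    score  rank
G0164|G0187 3.779382     1
G0088|G0204 3.508719     2
G0204|G0215 3.357744     3
```

The mean CV AUC of 0.87 says the ranker recovers most of the planted
druggability ordering at the default study conditions (moderate effects,
10% stage-label noise); the ranked table lists the candidate pairs best
first with their raw (uncalibrated) ranking scores. The same pipeline is
scriptable from a shell:

```bash
bspai simulate --seed 42 --out study/
bspai featurize --matrix study/matrix.mtx --genes study/genes.tsv \
    --cells study/barcodes.tsv --meta study/cell_meta.tsv \
    --gmt study/pathways.gmt --emb study/embeddings.tsv \
    --pairs study/gene_list.txt --out features.tsv
bspai train --model gbtree_pairwise --features features.tsv \
    --drugs study/drug_table.tsv --seed 42 --out model/
bspai rank --model model/model.pkl --features features.tsv --out ranked.tsv
bspai report --pair G0164,G0187 --model model/model.pkl \
    --features features.tsv --out report/
```

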