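# Methods

## Scope and data model

`bspai` consumes an *already annotated* single-cell expression matrix:
cells × genes counts (MatrixMarket triplet plus index files) with per-cell
`cell_type`, `tissue` ∈ {tumor, normal} and `patient` columns. Upstream
QC, normalization choices during clustering, and cell-type annotation are
out of scope; the package assumes the annotations are trustworthy. Cells
missing from the metadata table are dropped (logged); cells with a missing
tissue label are kept for activity and correlation features but excluded
from the safety feature, which is the only tissue-dependent quantity.

All expression-derived features are computed on a common scale, selected by
`RunConfig.normalization`:

- `cpm_log1p` (default): per-cell library size normalized to 10,000 counts,
  then log1p — the standard single-cell scale, making cells with different
  sequencing depths comparable;
- `counts`: the matrix as given, for callers that pre-normalize.

## Pair features

For an unordered pair (x, y), five feature groups:

**Safety.** Per gene, d = mean expression over tumor cells − mean over
normal cells (pseudo-bulk over all populations). The pair score is the
quasi-harmonic combination d_x·d_y/(d_x+d_y): symmetric, dominated by the
smaller difference, higher = more tumor-restricted. Two degeneracies are
defined away: |d_x+d_y| < 1e−12, and opposite-sign differences (where the
quasi-harmonic mean is not monotone in either argument) both yield 0 with a
warning. Same-sign negative pairs keep their (negative) value — a gene pair
enriched in normal tissue is actively unsafe, and the natural-language
binning has an "Unsafe" band below zero for exactly that case.

**Mechanism.** The count of pathways (GMT gene sets) containing both genes.
Genes absent from the database simply count 0; no enrichment statistic is
attempted because the downstream tree models only need a monotone signal.

**Gene embedding.** Euclidean distance between the genes' embedding
vectors. The table's dimensionality is whatever the file provides (200 for
Gene2Vec-style tables); nothing is hard-coded. Note the direction: small
distance = similar genes, so the language labels run "Very similar" at the
low end. A gene missing from the table yields a NaN sentinel on this
feature only.

**Activity.** A cell is positive for a gene when its expression strictly
exceeds the threshold T (`activity_threshold`, default 0 on the normalized
log scale — any detected expression counts; the data are zero-inflated
enough that 0 is a meaningful cutoff, and T is configurable for stricter
definitions). Per gene, the two (`top_k_populations`) cell types with the
highest mean expression are selected (ties broken lexicographically for
determinism), and P_gene is the **maximum** positive proportion over those
populations. The max — rather than the mean — is the only aggregate under
which the invariant `double_ratio_max ≤ single_ratio_max` is provable
(with the mean, a gene whose second population is silent can undercut a
double-positive population). Emitted aggregates: `single_ratio_sum`
(P_x + P_y), `single_ratio_min`, `single_ratio_max`, and
`double_ratio_max` — the largest fraction of cells with both genes positive
over the union of the two genes' top populations. Additionally, for every
focus population present in the data (default: exhausted CD8 T, Treg,
macrophage, epithelial — the tumor-microenvironment populations that matter
most for BsAb design), fixed-name variants `single_ratio_*@{cell_type}`,
`double_ratio@{cell_type}` and `pearson_r@{cell_type}` are emitted so the
feature-name list is identical for every pair in a run.

**Correlation.** Sample Pearson r of the two genes over all cells pooled
(default scope), plus per-focus-population variants. A zero-variance gene
yields r = 0 with a warning rather than NaN: "no linear association
measurable" is closer to 0 than to missing for the downstream models.

Missing features (absent gene, absent tissue compartment) are NaN
sentinels; tree models consume NaN natively, all other models receive
median imputation inside their pipelines.

## Labels and supervision

Clinical progress is a 5-level ordinal: 1 Approved/NDA/BLA, 2 Phase 3 (or
2/3), 3 Phase 1 (or 2), 4 Preclinical/IND, 5 Discontinued/pending — lower
code = more advanced. Free-text stage fields are keyword-mapped
case-insensitively. Each distinct pair's label is the *minimum* stage code
over its drugs (one success outweighs abandoned attempts); duplicate drug
ids with conflicting records keep the most advanced one (warned). The
binary positive class is stage 1 only ("will this pair be approved"),
configurable to {1, 2} for sensitivity analyses. Ordinal labels induce
preference pairs (winner with strictly smaller code) for learning-to-rank;
the full cross-stage set can be subsampled deterministically.

## Models

Seven fixed configurations (no hyperparameter search):

| kind | backing estimator | fixed settings |
|---|---|---|
| logistic_regression | sklearn LogisticRegression | C=0.1 (L2), max_iter=1000 |
| decision_tree | sklearn DecisionTreeClassifier | min_samples_leaf=5, max_depth=10 |
| random_forest | sklearn RandomForestClassifier | 100 trees |
| gradient_boosting | sklearn GradientBoostingClassifier | lr 0.1, 100 trees |
| neural_net | sklearn MLPClassifier | layers 256/128/64/32(/1), early stopping on a 10% split |
| gbtree_pointwise | XGBClassifier | lr 0.1, 100 trees, depth 10 |
| gbtree_pairwise | XGBRanker rank:pairwise | lr 0.1, 100 trees, depth 10 |

Notes on two settings that required interpretation: "L2 coefficient 0.1" is
read as the `C` parameter a practitioner sets in sklearn (the inverse
reading, λ=0.1 ⇒ C=10, regularizes 100× less; with only ~40 features the
choice is not critical). The neural configuration uses sklearn's MLP with
ReLU/Adam and early stopping — LeakyReLU, Dropout and Nadam are not
available there; the neural net is a comparison baseline, not the headline
model.

The pairwise ranker optimizes rank order of the relevance 6 − stage_code.
Query groups are the cross-validation fold ids of the training rows (one
group per fold) — pair order matters globally, and fold-sized groups keep
the objective's pair enumeration bounded. Its scores are **uncalibrated**
ranking values, not probabilities; AUC against the binary label is still
well defined (rank statistic) and is the benchmark metric.

Evaluation is stratified fivefold cross-validation; folds are assigned once
per dataset from the seed, shared across all configurations and ablation
prefixes so comparisons are paired. A fold lacking one class is skipped
with a warning and the mean is over valid folds. AUC is the rank-sum
formulation (`roc_auc_score`); the test suite pins it to brute-force
concordant-pair counting.

Split-frequency importance counts how often each feature is a split node
across the tree ensemble (XGBoost `weight`; node tally for sklearn
ensembles); non-tree models raise. The ablation protocol adds feature
groups cumulatively — double positive, safety, mechanism, embedding, pooled
single-cell expression, grouped per-cell-type variants — re-running CV on
identical folds per prefix.

## Natural-language reporting

The six headline features (embedding distance, safety score, Pearson r,
single_ratio_max, double_ratio_max, pathway co-occurrence) are discretized
into up to five equal-frequency bins fitted on the candidate-set
distribution: cut points at quantiles i/n_bins, left-open intervals, outer
intervals unbounded so every real value maps to exactly one label.
Duplicate quantiles (heavy ties) merge bins; the ordered label vocabulary
is then truncated to a centered contiguous run, and a constant feature
keeps only the middle label (warned). Bin edges are re-fit on each run's
candidates — they are data-derived quantities, not constants; a frozen
reference scheme is kept in the test suite purely as a regression fixture.

The prompt assembled from a pair's labels, glossary lines, model score and
rank ("Ranked r out of N candidates") is deterministic text. The default
renderer is an offline template producing a structured report (per-target
clinical-context sections, model-analysis bullets, conclusion); any object
with a `complete(prompt) -> str` method can be plugged in as an LLM client,
receives the prompt verbatim, and its reply is stored with provenance
metadata — on client failure the offline fallback is used and flagged.
No network access ever happens by default.

## Synthetic study generator

The generator emulates the statistical structure the method assumes, with
ground truth always returned:

- **Expression**: negative-binomial counts (gamma-Poisson, dispersion 0.5)
  with uniform dropout (rate 0.1), 2,000 cells over six cell types
  (exhausted CD8 T, Treg, macrophage, epithelial, fibroblast, B cell),
  60% tumor cells, 8 patients, 223 genes (the candidate membrane-protein
  list size implied by C(223,2) = 24,753 pairs). Gene baselines are
  log-normal with log-normal cell-type factors.
- **Planted signal** lives at the level where each quantity is defined, so
  pairs sharing a gene stay mutually consistent: every gene carries a
  tumor-specificity boost t_g ∈ [0,1] (tumor cells express it
  1 + 2.0·t_g times higher) and a home-population activity a_g (its home
  cell type expresses it 1 + 3.0·a_g times higher — genes homed together
  form co-expression blocks). Labeled pairs (600 drawn from the candidate
  set) are pulled together in the 200-d Gaussian embedding space with
  weight δ/(1+δ), δ = 4.0·u, and co-assigned to up to 4 shared pathways on
  top of a Bernoulli background (300 pathways, rate 0.04 ⇒ background
  expectation ≈ 0.5 shared pathways).
- **Latent druggability** of a labeled pair is the standardized sum of its
  rank-normalized planted components: quasi-harmonic tumor specificity of
  its genes, realized embedding proximity, realized shared-pathway count,
  and same-home co-activity (min a_g when the genes share a home, else 0).
  Components whose scale is set to 0 are excluded — zeroing all but one
  scale yields a study where exactly one feature group carries signal.
- **Drug table**: 791 drugs over the 600 labeled pairs (one per pair plus
  randomly assigned extras). Stages follow latent quintiles (top quintile =
  stage 1) and are flipped to a uniform random stage with probability
  `stage_noise` (default 0.1). Stage texts are drawn verbatim from the
  5-level vocabulary, so the whole table round-trips through the parser.

Effect scales were chosen once to produce *moderate* signal — each planted
component visibly but imperfectly recoverable from its feature (for
example, safety_score correlates ~0.5 with the planted tumor-specificity
component at default size) — giving a fivefold CV AUC around 0.87 for the
pairwise ranker at the default conditions.

What the generator does **not** emulate: batch/patient effects beyond a
patient id column, realistic gene-gene correlation outside the planted
blocks, matched tumor/adjacent-normal pairing within patients, ambient RNA
or doublets, and real cohort compositions. Passing tests therefore show
the pipeline recovers planted structure of the assumed form at realistic
noise levels — not that the features are biologically sufficient on real
cohorts.

## Numerical and reproducibility choices

- Everything stochastic derives from explicit integer seeds
  (`numpy.random.default_rng`, model `random_state`); single-threaded tree
  training; two runs with one seed are bit-identical.
- Tie-breaks are deterministic: lexicographic for top-population selection
  and ranking-score ties; stable sorts throughout.
- Degenerate inputs are defined, not crashed on: empty preference sets warn
  and return empty; CV folds lacking a class are skipped with a warning;
  constant features bin to a single middle label.
- Default problem sizes (2,000 cells, 223 genes, 600 labeled pairs, 5
  folds) keep a full study-simulate-train-evaluate cycle in the low
  seconds on one core, which is what makes the multi-seed consistency
  checks in the test suite practical.

## Known limitations

- The safety score's opposite-sign policy discards the mixed-direction
  information entirely; a signed alternative (e.g. min(d_x, d_y)) may rank
  such pairs better but would no longer match the stated formula.
- Pathway co-occurrence is a raw count, uncorrected for pathway size or
  gene promiscuity.
- The pairwise ranker's scores are not comparable across retrainings and
  carry no probability semantics; rank and within-run score gaps are the
  meaningful outputs.
- With up to five bins fitted on heavy-tailed features, the extreme labels
  can cover wide value ranges; the direction notes in the binning scheme
  are part of the contract and should be surfaced to report readers.
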