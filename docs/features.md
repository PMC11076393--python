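# Feature-table columns

`bspai featurize` (and `PairFeaturizer.transform`) emit one row per pair,
indexed by the canonical pair string `geneA|geneB` (lexicographic order),
with this fixed column order:

| column | range | meaning |
|---|---|---|
| `safety_score` | ℝ (NaN if a tissue compartment is absent) | quasi-harmonic mean d_x·d_y/(d_x+d_y) of per-gene tumor−normal pseudo-bulk differences; higher = safer; 0 for degenerate (opposite-sign or zero-sum) differences |
| `cooccurrence_count` | ℕ (NaN without a pathway DB) | pathways containing both genes |
| `embedding_distance` | ≥ 0 (NaN if a gene lacks a vector) | Euclidean distance between embedding vectors; **small = similar** |
| `pearson_r` | [−1, 1] | Pearson correlation across all cells pooled; 0 for zero-variance genes |
| `single_ratio_sum` | [0, 2] | P_x + P_y, where P_gene = max positive proportion over the gene's top-k populations |
| `single_ratio_min` | [0, 1] | min(P_x, P_y) |
| `single_ratio_max` | [0, 1] | max(P_x, P_y) |
| `double_ratio_max` | [0, 1] | max double-positive proportion over the union of both genes' top-k populations; always ≤ `single_ratio_max` |

Then, for every focus cell type `ct` present in the matrix (default order:
exhausted CD8 T, Treg, macrophage, epithelial):

| column | meaning |
|---|---|
| `single_ratio_sum@ct`, `single_ratio_min@ct`, `single_ratio_max@ct` | the same statistics computed within `ct` only |
| `double_ratio@ct` | double-positive proportion within `ct` |
| `pearson_r@ct` | Pearson r within `ct` (omitted when `pearson_per_population=False`) |

Ablation feature groups partition these columns: `double_positive` =
{double_ratio_max}; `safety` = {safety_score}; `mechanism` =
{cooccurrence_count}; `embedding` = {embedding_distance};
`single_cell_expression` = the remaining pooled columns;
`grouped_cell_type` = every `@ct` column.
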