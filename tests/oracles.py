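"""Independent brute-force oracles, written against plain arrays and loops.

These deliberately avoid the package's vectorized code paths (and numpy
reductions where a plain loop is feasible) so they can serve as an
independent check of every feature formula and of the AUC statistic.
"""

from __future__ import annotations

import math


def oracle_tissue_diff(X, tissues, j):
    """Tumor-minus-normal mean of column j; X is a dense row-major 2-D list/array."""
    tumor, normal = [], []
    for i, t in enumerate(tissues):
        if t == "tumor":
            tumor.append(X[i][j])
        elif t == "normal":
            normal.append(X[i][j])
    return sum(tumor) / len(tumor) - sum(normal) / len(normal)


def oracle_safety(d_x, d_y):
    """Quasi-harmonic safety combination, mirroring the documented degeneracy policy."""
    if abs(d_x + d_y) < 1e-12:
        return 0.0
    if (d_x > 0 and d_y < 0) or (d_x < 0 and d_y > 0):
        return 0.0
    return d_x * d_y / (d_x + d_y)


def oracle_euclidean(u, v):
    total = 0.0
    for a, b in zip(u, v):
        total += (a - b) ** 2
    return math.sqrt(total)


def oracle_positive_proportion(X, cell_types, j, cell_type, threshold):
    count, n = 0, 0
    for i, ct in enumerate(cell_types):
        if ct == cell_type:
            n += 1
            if X[i][j] > threshold:
                count += 1
    return count / n


def oracle_double_positive(X, cell_types, ja, jb, cell_type, threshold):
    count, n = 0, 0
    for i, ct in enumerate(cell_types):
        if ct == cell_type:
            n += 1
            if X[i][ja] > threshold and X[i][jb] > threshold:
                count += 1
    return count / n


def oracle_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    denom = math.sqrt(sum((xi - mx) ** 2 for xi in x)) * math.sqrt(
        sum((yi - my) ** 2 for yi in y)
    )
    if denom < 1e-12:
        return 0.0
    return num / denom


def oracle_cooccurrence(pathways, gene_a, gene_b):
    """pathways: mapping name -> iterable of genes."""
    count = 0
    for genes in pathways.values():
        gs = set(genes)
        if gene_a in gs and gene_b in gs:
            count += 1
    return count


def oracle_auc(labels, scores):
    """Concordant-pair count (ties worth 1/2) over positive x negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_top_populations(X, cell_types, j, k):
    """k cell types with highest mean of column j; ties lexicographic."""
    sums: dict[str, list[float]] = {}
    for i, ct in enumerate(cell_types):
        sums.setdefault(ct, []).append(X[i][j])
    means = {ct: sum(v) / len(v) for ct, v in sums.items()}
    ranked = sorted(means, key=lambda ct: (-means[ct], ct))
    return ranked[: min(k, len(ranked))]
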