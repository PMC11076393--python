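import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bspai.features import (
    PairFeaturizer,
    build_feature_vector,
    compute_activity_features,
    compute_cooccurrence,
    compute_embedding_distance,
    compute_pearson,
    compute_safety_score,
    double_positive_proportion,
    feature_groups,
    positive_proportion,
    pseudo_bulk_mean,
    safety_from_differences,
    select_top_populations,
)
from bspai.types import GenePair, GeneEmbeddingTable, PathwayDB, RunConfig

from .conftest import make_matrix
from .oracles import oracle_euclidean, oracle_pearson

PAIR = GenePair("g0", "g1")


class TestSafety:
    def test_symmetric_case(self):
        assert safety_from_differences(2.0, 2.0) == pytest.approx(1.0)

    def test_zero_numerator(self):
        assert safety_from_differences(0.0, 5.0) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert safety_from_differences(3.0, 6.0) == pytest.approx(2.0)

    def test_opposite_signs_degenerate(self, caplog):
        with caplog.at_level("WARNING", logger="bspai"):
            assert safety_from_differences(-1.0, 3.0) == 0.0

    def test_pseudo_bulk_mean_uses_requested_tissue(self):
        matrix = make_matrix(
            [[1], [2], [3], [10]], tissues=["tumor", "tumor", "normal", "normal"]
        )
        assert pseudo_bulk_mean(matrix, "g0", "tumor") == pytest.approx(1.5)
        assert pseudo_bulk_mean(matrix, "g0", "normal") == pytest.approx(6.5)

    def test_zero_expression_gives_zero_mean(self):
        matrix = make_matrix([[0], [0]], tissues=["tumor", "tumor"])
        assert pseudo_bulk_mean(matrix, "g0", "tumor") == 0.0

    def test_missing_tissue_instructs_skip(self):
        matrix = make_matrix([[1], [2]], tissues=["tumor", "tumor"])
        with pytest.raises(ValueError, match="skip the safety feature"):
            pseudo_bulk_mean(matrix, "g0", "normal")

    def test_pair_symmetry(self):
        matrix = make_matrix(
            [[1, 5], [3, 2], [0, 1], [2, 0]],
            tissues=["tumor", "tumor", "normal", "normal"],
        )
        assert compute_safety_score(matrix, PAIR) == pytest.approx(
            compute_safety_score(matrix, GenePair("g1", "g0"))
        )


class TestMechanismAndEmbedding:
    def test_cooccurrence_counts_shared_pathways(self):
        db = PathwayDB({"P1": {"g0", "g1", "g2"}, "P2": {"g0", "g1"}, "P3": {"g0", "g2"}})
        assert compute_cooccurrence(PAIR, db) == 2

    def test_absent_gene_counts_zero(self):
        db = PathwayDB({"P1": {"a", "b"}})
        assert compute_cooccurrence(PAIR, db) == 0

    def test_distance_345(self):
        emb = GeneEmbeddingTable({"g0": [0.0, 0.0], "g1": [3.0, 4.0]})
        assert compute_embedding_distance(PAIR, emb) == pytest.approx(5.0)

    def test_distance_identity(self):
        emb = GeneEmbeddingTable({"g0": [1.0, 2.0], "g1": [1.0, 2.0]})
        assert compute_embedding_distance(PAIR, emb) == 0.0

    def test_distance_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        u, v = rng.normal(size=10), rng.normal(size=10)
        emb = GeneEmbeddingTable({"g0": u, "g1": v})
        assert compute_embedding_distance(PAIR, emb) == pytest.approx(
            oracle_euclidean(u, v), abs=1e-12
        )

    @settings(derandomize=True, max_examples=30)
    @given(
        vecs=hnp.arrays(
            float,
            (3, 4),
            elements=st.floats(-10, 10, allow_nan=False),
        )
    )
    def test_triangle_inequality(self, vecs):
        emb = GeneEmbeddingTable({"a": vecs[0], "b": vecs[1], "c": vecs[2]})
        dab = compute_embedding_distance(GenePair("a", "b"), emb)
        dbc = compute_embedding_distance(GenePair("b", "c"), emb)
        dac = compute_embedding_distance(GenePair("a", "c"), emb)
        assert dac <= dab + dbc + 1e-9


class TestActivity:
    def test_all_above_threshold(self):
        matrix = make_matrix([[2], [3], [4]])
        assert positive_proportion(matrix, "g0", "T", 1.0) == 1.0

    def test_threshold_above_max_gives_zero(self):
        matrix = make_matrix([[2], [3], [4]])
        assert positive_proportion(matrix, "g0", "T", 100.0) == 0.0

    def test_two_of_five(self):
        matrix = make_matrix([[0], [1], [2], [3], [0]])
        assert positive_proportion(matrix, "g0", "T", 1.5) == pytest.approx(0.4)

    def test_threshold_is_strict(self):
        matrix = make_matrix([[1], [1]])
        assert positive_proportion(matrix, "g0", "T", 1.0) == 0.0

    def test_double_disjoint_positives(self):
        matrix = make_matrix([[2, 0], [0, 2]])
        assert double_positive_proportion(matrix, PAIR, "T", 0.0) == 0.0

    def test_double_absorbing_case(self):
        matrix = make_matrix([[2, 0], [3, 2], [1, 5]])
        assert double_positive_proportion(matrix, PAIR, "T", 0.0) == positive_proportion(
            matrix, "g1", "T", 0.0
        )

    def test_empty_population_rejected(self):
        matrix = make_matrix([[1]])
        with pytest.raises(ValueError, match="no cells"):
            positive_proportion(matrix, "g0", "NK", 0.0)

    @settings(derandomize=True, max_examples=25)
    @given(data=st.data())
    def test_double_bounded_by_min_single(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        values = rng.poisson(1.0, size=(20, 2)).astype(float)
        matrix = make_matrix(values)
        threshold = data.draw(st.floats(0, 3))
        double = double_positive_proportion(matrix, PAIR, "T", threshold)
        singles = [positive_proportion(matrix, g, "T", threshold) for g in PAIR]
        assert double <= min(singles) + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), t1=st.floats(0, 5), t2=st.floats(0, 5))
    def test_monotone_in_threshold(self, seed, t1, t2):
        lo, hi = sorted([t1, t2])
        values = np.random.default_rng(seed).poisson(2.0, size=(15, 1)).astype(float)
        matrix = make_matrix(values)
        assert positive_proportion(matrix, "g0", "T", hi) <= positive_proportion(
            matrix, "g0", "T", lo
        )


class TestTopPopulations:
    def test_dominant_population_first(self):
        matrix = make_matrix(
            [[5], [5], [0], [0]], cell_types=["Tcell", "Tcell", "B", "NK"]
        )
        top = select_top_populations(matrix, "g0", 2)
        assert top[0] == "Tcell" and len(top) == 2

    def test_ties_break_lexicographically(self):
        matrix = make_matrix([[1], [1]], cell_types=["zeta", "alpha"])
        assert select_top_populations(matrix, "g0", 2) == ["alpha", "zeta"]

    def test_matches_oracle_sort(self):
        from .oracles import oracle_top_populations

        rng = np.random.default_rng(11)
        values = rng.poisson(2.0, size=(40, 1)).astype(float)
        types = [f"ct{int(k)}" for k in rng.integers(0, 4, 40)]
        matrix = make_matrix(values, cell_types=types)
        assert select_top_populations(matrix, "g0", 3) == oracle_top_populations(
            values, types, 0, 3
        )

    def test_fewer_populations_than_k_warns(self, caplog):
        matrix = make_matrix([[1], [2]], cell_types=["A", "A"])
        with caplog.at_level("WARNING", logger="bspai"):
            assert select_top_populations(matrix, "g0", 3) == ["A"]


class TestPearson:
    def test_perfect_positive(self):
        matrix = make_matrix([[1, 1], [2, 2], [3, 3], [4, 4]])
        assert compute_pearson(matrix, PAIR) == pytest.approx(1.0)

    def test_perfect_negative(self):
        matrix = make_matrix([[1, 4], [2, 3], [3, 2], [4, 1]])
        assert compute_pearson(matrix, PAIR) == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(10, 2)) ** 2
        matrix = make_matrix(values)
        assert compute_pearson(matrix, PAIR) == pytest.approx(
            oracle_pearson(values[:, 0], values[:, 1]), abs=1e-12
        )

    def test_zero_variance_recorded_as_zero(self, caplog):
        matrix = make_matrix([[1, 1], [1, 2], [1, 3]])
        with caplog.at_level("WARNING", logger="bspai"):
            assert compute_pearson(matrix, PAIR) == 0.0

    def test_too_few_cells_rejected(self):
        matrix = make_matrix([[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="at least 3"):
            compute_pearson(matrix, PAIR)

    @settings(derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 50),
        shift=st.floats(0, 100),  # expression stays non-negative
    )
    def test_invariant_under_positive_affine_transform(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        values = rng.poisson(3.0, size=(12, 2)).astype(float)
        if values[:, 0].std() == 0 or values[:, 1].std() == 0:
            return
        r_base = compute_pearson(make_matrix(values), PAIR)
        transformed = values.copy()
        transformed[:, 0] = scale * transformed[:, 0] + shift
        r_affine = compute_pearson(make_matrix(transformed), PAIR)
        assert r_affine == pytest.approx(r_base, abs=1e-9)


class TestActivityFeatures:
    CFG = RunConfig(normalization="counts", focus_cell_types=("Tcell", "B"))

    def test_silent_genes_give_zero_everywhere(self):
        matrix = make_matrix(np.zeros((8, 2)), cell_types=["Tcell", "B"] * 4)
        feats = compute_activity_features(matrix, PAIR, self.CFG)
        assert all(v == 0.0 for v in feats.values())

    def test_order_statistics_consistent(self):
        rng = np.random.default_rng(9)
        matrix = make_matrix(
            rng.poisson(1.0, size=(30, 2)).astype(float),
            cell_types=[["Tcell", "B", "NK"][int(k)] for k in rng.integers(0, 3, 30)],
        )
        feats = compute_activity_features(matrix, PAIR, self.CFG)
        assert feats["single_ratio_min"] <= feats["single_ratio_max"]
        assert feats["double_ratio_max"] <= feats["single_ratio_max"] + 1e-12
        assert feats["single_ratio_sum"] == pytest.approx(
            feats["single_ratio_min"] + feats["single_ratio_max"]
        )

    def test_focus_population_variants_emitted(self):
        matrix = make_matrix([[1, 0], [0, 1]], cell_types=["Tcell", "B"])
        feats = compute_activity_features(matrix, PAIR, self.CFG)
        assert "double_ratio@Tcell" in feats and "single_ratio_max@B" in feats


class TestFeaturizer:
    def _resources(self, seed=0, n_cells=40, n_genes=5):
        rng = np.random.default_rng(seed)
        values = rng.poisson(1.5, size=(n_cells, n_genes)).astype(float)
        types = [["Tcell", "B", "NK"][int(k)] for k in rng.integers(0, 3, n_cells)]
        tissues = ["tumor" if k else "normal" for k in rng.integers(0, 2, n_cells)]
        tissues[0], tissues[1] = "tumor", "normal"
        matrix = make_matrix(values, cell_types=types, tissues=tissues)
        genes = list(matrix.gene_index)
        emb = GeneEmbeddingTable({g: rng.standard_normal(8) for g in genes[:-1]})
        db = PathwayDB({"P1": set(genes[:3]), "P2": set(genes[1:4]), "P3": {genes[0], genes[2]}})
        return matrix, db, emb

    def test_deterministic(self):
        matrix, db, emb = self._resources()
        fz = PairFeaturizer(normalization="counts", focus_cell_types=("Tcell",))
        fz.fit(matrix, pathways=db, embeddings=emb)
        pairs = [GenePair("g0", "g1"), GenePair("g2", "g3")]
        a = fz.transform(pairs)
        b = fz.transform(pairs)
        assert a.equals(b)

    def test_missing_embedding_isolated_to_one_feature(self):
        matrix, db, emb = self._resources()
        last = list(matrix.gene_index)[-1]
        fz = PairFeaturizer(normalization="counts").fit(matrix, pathways=db, embeddings=emb)
        row = fz.transform([GenePair("g0", last)]).iloc[0]
        assert np.isnan(row["embedding_distance"])
        assert not np.isnan(row["safety_score"])
        assert not np.isnan(row["double_ratio_max"])

    def test_agrees_with_single_pair_operations(self):
        matrix, db, emb = self._resources(seed=4)
        cfg = RunConfig(normalization="counts", focus_cell_types=("Tcell", "B"))
        pair = GenePair("g1", "g2")
        row = build_feature_vector(pair, matrix, db, emb, cfg)
        assert row["safety_score"] == pytest.approx(compute_safety_score(matrix, pair), abs=1e-12)
        assert row["cooccurrence_count"] == compute_cooccurrence(pair, db)
        assert row["embedding_distance"] == pytest.approx(
            compute_embedding_distance(pair, emb), abs=1e-12
        )
        assert row["pearson_r"] == pytest.approx(compute_pearson(matrix, pair), abs=1e-12)
        activity = compute_activity_features(matrix, pair, cfg)
        for name, value in activity.items():
            assert row[name] == pytest.approx(value, abs=1e-12), name

    def test_feature_names_stable_across_pairs(self):
        matrix, db, emb = self._resources()
        fz = PairFeaturizer(normalization="counts").fit(matrix, pathways=db, embeddings=emb)
        table = fz.transform([GenePair("g0", "g1"), GenePair("g1", "g3")])
        assert list(table.columns) == fz.feature_names_

    def test_pair_symmetry_of_features(self):
        matrix, db, emb = self._resources(seed=8)
        fz = PairFeaturizer(normalization="counts").fit(matrix, pathways=db, embeddings=emb)
        fwd = fz.transform([GenePair("g0", "g1")]).iloc[0]
        rev = fz.transform([GenePair("g1", "g0")]).iloc[0]
        assert fwd.equals(rev)


class TestFeatureGroups:
    def test_partition_covers_all_names(self):
        names = [
            "safety_score",
            "cooccurrence_count",
            "embedding_distance",
            "pearson_r",
            "single_ratio_sum",
            "single_ratio_min",
            "single_ratio_max",
            "double_ratio_max",
            "double_ratio@Treg",
            "pearson_r@Treg",
        ]
        groups = feature_groups(names)
        flattened = [n for g in groups.values() for n in g]
        assert sorted(flattened) == sorted(names)
        assert groups["double_positive"] == ["double_ratio_max"]
        assert set(groups["grouped_cell_type"]) == {"double_ratio@Treg", "pearson_r@Treg"}
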