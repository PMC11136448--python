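"""Annotation pipeline: sampling, matching, MNN, k-NN, the full run."""

import numpy as np
import pytest

import gatescribe as g
from gatescribe import errors
from gatescribe.annotate import build_confident_sets, simple_random_sample
from gatescribe.signature import SignatureMatrix
from gatescribe.tables import build_dictionary, table_from_strings


class TestSRS:
    def test_size_contract(self):
        idx = simple_random_sample(10_000, 0.1, seed=0)
        assert len(idx) == 1000 and len(set(idx)) == 1000

    def test_fraction_one_is_identity(self):
        np.testing.assert_array_equal(simple_random_sample(50, 1.0, 0), np.arange(50))

    def test_floor_engages(self):
        assert len(simple_random_sample(2000, 0.05, 0)) == 500

    def test_floor_capped_at_n(self):
        assert len(simple_random_sample(40, 0.5, 0)) == 40

    def test_bad_fraction(self):
        with pytest.raises(errors.ParameterError):
            simple_random_sample(10, 0.0, 0)


class TestMatchSignatures:
    def _sig(self, rows, markers):
        return SignatureMatrix(levels=np.array(rows, dtype="<U1"), marker_names=markers)

    def test_exact_and_unclassified(self):
        table = table_from_strings({"T": "A+,B-"}, ["A", "B"])
        d = build_dictionary(table)
        sig = self._sig([["+", "-"], ["-", "-"]], ["A", "B"])
        assert g.match_signatures(sig, d) == ["T", "unclassified"]

    def test_priority_resolution_matches_brute_force(self):
        rng = np.random.default_rng(8)
        universe = ["A", "B", "C"]
        table = table_from_strings(
            {"T1": "A+", "T2": "A+,B-", "T3": "B-,C+", "T4": "A-"}, universe
        )
        d = build_dictionary(table)
        records = d.records()
        rows = [[rng.choice(["-", "+"]) for _ in universe] for _ in range(100)]
        sig = self._sig(rows, universe)
        got = g.match_signatures(sig, d)
        for row, label in zip(rows, got):
            brute = next((ct for s, ct, _ in records if s == tuple(row)), None)
            assert label == (brute or "unclassified")

    def test_missing_marker_rejected(self):
        table = table_from_strings({"T": "A+,Z-"}, ["A", "Z"])
        d = build_dictionary(table)
        sig = self._sig([["+"]], ["A"])
        with pytest.raises(errors.SpecificationError, match="Z"):
            g.match_signatures(sig, d)


class TestMNN:
    def test_one_dimensional_example(self):
        pairs = g.mutual_nearest_neighbors(
            np.array([[0.0], [1.0]]), np.array([[0.4]]), k=1
        )
        assert pairs == {(0, 0)}

    def test_empty_side(self):
        assert g.mutual_nearest_neighbors(np.empty((0, 2)), np.ones((3, 2)), 3) == set()

    def test_matches_brute_force(self):
        """MNN pairs equal the all-pairs definition on random point sets."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            na, nu, k, dim = rng.integers(5, 60), rng.integers(5, 60), rng.integers(1, 10), 3
            X_a = rng.normal(size=(na, dim))
            X_u = rng.normal(size=(nu, dim))
            got = g.mutual_nearest_neighbors(X_a, X_u, int(k))
            dist = np.linalg.norm(X_a[:, None, :] - X_u[None, :, :], axis=2)
            expected = set()
            for i in range(na):
                knn_i = set(np.argsort(dist[i], kind="stable")[:k])
                for j in range(nu):
                    knn_j = set(np.argsort(dist[:, j], kind="stable")[:k])
                    if j in knn_i and i in knn_j:
                        expected.add((i, j))
            assert got == expected

    def test_monotone_in_k(self):
        rng = np.random.default_rng(10)
        X_a, X_u = rng.normal(size=(30, 2)), rng.normal(size=(25, 2))
        small = g.mutual_nearest_neighbors(X_a, X_u, 3)
        large = g.mutual_nearest_neighbors(X_a, X_u, 6)
        assert small <= large


class TestConfidentSets:
    def test_no_pairs_keeps_annotated(self):
        conf_a, conf_u = build_confident_sets(3, 2, set(), k=10)
        assert conf_a.all() and conf_u.all()

    def test_paired_unclassified_excluded(self):
        _, conf_u = build_confident_sets(2, 3, {(0, 1)}, k=10)
        assert list(conf_u) == [True, False, True]

    def test_ambiguity_threshold(self):
        pairs = {(0, j) for j in range(6)}  # 6 of k=10 pairs -> ambiguous
        conf_a, _ = build_confident_sets(2, 8, pairs, k=10)
        assert list(conf_a) == [False, True]
        conf_a, _ = build_confident_sets(2, 8, {(0, j) for j in range(5)}, k=10)
        assert list(conf_a) == [True, True]  # exactly half is not "higher"


class TestKNNRefine:
    def test_single_training_point(self):
        out = g.knn_refine(np.zeros((1, 2)), ["L"], np.random.default_rng(0).normal(size=(5, 2)), k=3)
        assert out == ["L"] * 5

    def test_tie_breaks_to_nearest(self):
        X_train = np.array([[0.0], [1.0]])
        out = g.knn_refine(X_train, ["A", "B"], np.array([[0.4]]), k=2)
        assert out == ["A"]

    def test_separated_clusters_fully_correct(self):
        rng = np.random.default_rng(11)
        X_train = np.vstack([rng.normal(-5, 0.3, (100, 1)), rng.normal(5, 0.3, (100, 1))])
        labels = ["neg"] * 100 + ["pos"] * 100
        X_query = np.vstack([rng.normal(-5, 0.3, (100, 1)), rng.normal(5, 0.3, (100, 1))])
        out = g.knn_refine(X_train, labels, X_query, k=10)
        assert out == ["neg"] * 100 + ["pos"] * 100

    def test_empty_training_rejected(self):
        with pytest.raises(errors.ParameterError):
            g.knn_refine(np.empty((0, 2)), [], np.ones((1, 2)), 1)


class TestAnnotatePipeline:
    def test_sampled_pipeline_accuracy(self, small_dataset):
        spec, matrix, labels = small_dataset
        ann = g.annotate(matrix, spec.table, g.AnnotationParams(srs_fraction=0.1, seed=1))
        assert g.overall_accuracy(ann, labels) >= 95.0

    def test_full_sampling_no_refinement_equals_matching(self, small_dataset):
        """With every cell sampled and matched, refinement is a no-op."""
        spec, matrix, _ = small_dataset
        from gatescribe.signature import build_signature_matrix
        from gatescribe.tables import required_levels

        ann = g.annotate(matrix, spec.table, g.AnnotationParams(srs_fraction=1.0, seed=2))
        sig, _ = build_signature_matrix(matrix, required_levels(spec.table), seed=2)
        direct = g.match_signatures(sig, build_dictionary(spec.table))
        matched = [d != "unclassified" for d in direct]
        assert all(
            a == d for a, d, ok in zip(ann.labels, direct, matched) if ok
        )
        if all(matched):
            assert ann.labels == direct

    def test_partition_and_provenance(self, small_dataset):
        spec, matrix, _ = small_dataset
        ann = g.annotate(matrix, spec.table, g.AnnotationParams(srs_fraction=0.2, seed=3))
        assert len(ann) == matrix.n_cells
        counts = {}
        for p in ann.provenance:
            counts[p] = counts.get(p, 0) + 1
        assert sum(counts.values()) == matrix.n_cells
        assert set(counts) <= {"direct", "refined", "unknown", "unsampled->refined"}

    def test_reject_option_flags_planted_population(self):
        spec = g.standard_spec(n_cells=4000, seed=12, unknown_fraction=0.1)
        matrix, labels = g.generate_dataset(spec)
        ann = g.annotate(
            matrix, spec.table, g.AnnotationParams(seed=12, reject_option=True)
        )
        ref = np.array(labels.labels)
        pred = np.array(ann.labels)
        planted = ref == "unknown"
        assert (pred[planted] == "unknown").mean() >= 0.8
        assert (pred[~planted] == "unknown").mean() <= 0.02

    def test_missing_marker_named_in_error(self, small_dataset):
        _, matrix, _ = small_dataset
        table = table_from_strings({"T": "NotAMarker+"}, ["NotAMarker"])
        with pytest.raises(errors.SpecificationError, match="NotAMarker"):
            g.annotate(matrix, table)

    def test_seed_determinism(self, small_dataset):
        spec, matrix, _ = small_dataset
        p = g.AnnotationParams(srs_fraction=0.1, seed=21)
        a = g.annotate(matrix, spec.table, p)
        b = g.annotate(matrix, spec.table, p)
        assert a.labels == b.labels and a.provenance == b.provenance
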