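"""Reflective random indexing: elemental vectors, weighting, reflection, k-NN."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenospread import (
    ElementalVectorStore,
    ParameterError,
    SemanticVectorStore,
    build_concept_vectors,
    build_document_vectors,
    build_semantic_vectors,
    cosine,
    log_entropy_weights,
    make_elemental_vector,
    nearest_neighbors,
)
from conftest import make_corpus


class TestElementalVectors:
    def test_deterministic(self):
        a = make_elemental_vector("C0006142", dim=1000, nonzeros=10, master_seed=42)
        b = make_elemental_vector("C0006142", dim=1000, nonzeros=10, master_seed=42)
        np.testing.assert_array_equal(a, b)

    def test_generation_order_does_not_matter(self):
        store = ElementalVectorStore(dim=64, nonzeros=4, master_seed=1)
        first = store.vector("C2").copy()
        store.vector("C1")
        np.testing.assert_array_equal(store.vector("C2"), first)

    def test_forced_structure_dim_equals_nonzeros(self):
        v = make_elemental_vector("C1", dim=4, nonzeros=4, master_seed=0)
        assert sorted(v) == [-1.0, -1.0, 1.0, 1.0]

    def test_balanced_sign_counts(self):
        v = make_elemental_vector("C7", dim=1000, nonzeros=10, master_seed=3)
        assert int((v == 1).sum()) == 5
        assert int((v == -1).sum()) == 5
        assert int((v == 0).sum()) == 990

    @pytest.mark.parametrize("dim,nonzeros", [(100, 3), (100, 0), (10, 12)])
    def test_bad_parameters_rejected(self, dim, nonzeros):
        with pytest.raises(ParameterError):
            make_elemental_vector("C1", dim=dim, nonzeros=nonzeros)

    def test_near_orthogonality_brute_force(self):
        # all 4950 pairwise cosines among 100 elemental vectors, by brute force
        vecs = [
            make_elemental_vector(f"C{i}", dim=1000, nonzeros=10, master_seed=0)
            for i in range(1, 101)
        ]
        cosines = [
            abs(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
            for a, b in itertools.combinations(vecs, 2)
        ]
        assert len(cosines) == 4950
        assert float(np.mean(cosines)) < 0.05


class TestLogEntropyWeights:
    def test_single_occurrence_has_weight_one(self):
        docs = [("p1", f"d{j}", [("C1", 100)]) for j in range(1, 11)]
        docs[0] = ("p1", "d1", [("C1", 100), ("C2", 100)])
        weights = log_entropy_weights(make_corpus(docs))
        assert weights["C2"] == pytest.approx(1.0)

    def test_uniform_occurrence_has_weight_zero(self):
        docs = [("p1", f"d{j}", [("C1", 100)]) for j in range(1, 11)]
        weights = log_entropy_weights(make_corpus(docs))
        assert weights["C1"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_oracle(self):
        # n=3 documents, tf = (2, 1, 0):
        # g = 1 + [(2/3)ln(2/3) + (1/3)ln(1/3)] / ln(3) = 0.42061983571430506
        corpus = make_corpus(
            [
                ("p1", "d1", [("C1", 100), ("C1", 100), ("C9", 5)]),
                ("p1", "d2", [("C1", 100), ("C9", 5)]),
                ("p1", "d3", [("C9", 5)]),
            ]
        )
        weights = log_entropy_weights(corpus)
        assert weights["C1"] == pytest.approx(0.42061983571430506, abs=1e-12)

    def test_single_document_corpus_convention(self):
        weights = log_entropy_weights(make_corpus([("p1", "d1", [("C1", 10), ("C2", 20)])]))
        assert weights == {"C1": 1.0, "C2": 1.0}

    @given(
        st.lists(
            st.lists(st.integers(1, 8), min_size=1, max_size=6),
            min_size=1,
            max_size=8,
        )
    )
    def test_weights_in_unit_interval(self, doc_cuis):
        corpus = make_corpus(
            [
                (f"p1", f"d{j}", [(f"C{c}", 100) for c in cuis])
                for j, cuis in enumerate(doc_cuis)
            ]
        )
        for g in log_entropy_weights(corpus).values():
            assert -1e-12 <= g <= 1.0 + 1e-12


class TestDocumentVectors:
    def test_single_cui_doc_equals_normalized_elemental(self):
        corpus = make_corpus([("p1", "d1", [("C1", 500)]), ("p1", "d2", [("C2", 500)])])
        elemental = ElementalVectorStore(dim=64, nonzeros=4, master_seed=0)
        docs = build_document_vectors(corpus, elemental, log_entropy_weights(corpus))
        e = elemental.vector("C1")
        np.testing.assert_allclose(
            docs.vector("p1", "d1"), e / np.linalg.norm(e), atol=1e-12
        )

    def test_fully_deweighted_doc_is_zero_with_warning(self, caplog):
        # C1 occurs once in each of the 3 docs -> g = 0 -> d3 is all-zero
        corpus = make_corpus(
            [
                ("p1", "d1", [("C1", 10), ("C2", 10)]),
                ("p1", "d2", [("C1", 10), ("C3", 10)]),
                ("p1", "d3", [("C1", 10)]),
            ]
        )
        elemental = ElementalVectorStore(dim=32, nonzeros=4, master_seed=0)
        with caplog.at_level("WARNING"):
            docs = build_document_vectors(corpus, elemental, log_entropy_weights(corpus))
        assert np.linalg.norm(docs.vector("p1", "d3")) == 0.0
        assert "zero vector" in caplog.text

    def test_two_cui_doc_matches_brute_force(self):
        corpus = make_corpus(
            [
                ("p1", "d1", [("C1", 10), ("C2", 10), ("C2", 10)]),
                ("p1", "d2", [("C1", 10), ("C3", 10)]),
                ("p1", "d3", [("C3", 10)]),
            ]
        )
        elemental = ElementalVectorStore(dim=8, nonzeros=2, master_seed=5)
        weights = log_entropy_weights(corpus)
        docs = build_document_vectors(corpus, elemental, weights)
        # independent brute force for d1: log(1+tf) * g * elemental, normalized
        raw = (
            math.log(2) * weights["C1"] * elemental.vector("C1")
            + math.log(3) * weights["C2"] * elemental.vector("C2")
        )
        np.testing.assert_allclose(
            docs.vector("p1", "d1"), raw / np.linalg.norm(raw), atol=1e-12
        )


class TestConceptVectors:
    def _toy(self):
        corpus = make_corpus(
            [
                ("p1", "d1", [("C1", 10), ("C2", 10)]),
                ("p1", "d2", [("C2", 10), ("C3", 10)]),
                ("p2", "d1", [("C3", 10), ("C4", 10)]),
                ("p2", "d2", [("C4", 10), ("C5", 10), ("C5", 10)]),
                ("p3", "d1", [("C5", 10), ("C1", 10)]),
            ]
        )
        elemental = ElementalVectorStore(dim=32, nonzeros=4, master_seed=2)
        weights = log_entropy_weights(corpus)
        docs = build_document_vectors(corpus, elemental, weights)
        return corpus, docs

    def test_single_document_concept_equals_document_vector(self):
        corpus = make_corpus(
            [("p1", "d1", [("C1", 10)]), ("p1", "d2", [("C2", 10), ("C3", 10)])]
        )
        elemental = ElementalVectorStore(dim=32, nonzeros=4, master_seed=0)
        docs = build_document_vectors(corpus, elemental, log_entropy_weights(corpus))
        store = build_concept_vectors(corpus, docs)
        np.testing.assert_allclose(
            store.vector("C1"), docs.vector("p1", "d1"), atol=1e-12
        )

    def test_all_nonzero_vectors_unit_norm(self):
        corpus, docs = self._toy()
        store = build_concept_vectors(corpus, docs)
        for cui in store.cuis():
            n = np.linalg.norm(store.vector(cui))
            assert n == pytest.approx(1.0, abs=1e-9) or n == 0.0

    def test_five_doc_corpus_matches_brute_force(self):
        corpus, docs = self._toy()
        store = build_concept_vectors(corpus, docs)
        # independent recomputation: binary document membership, then normalize
        for cui in sorted(corpus.vocabulary):
            raw = np.zeros(32)
            for doc in corpus:
                if cui in {m.cui for m in doc.mentions}:
                    raw += docs.vector(doc.patient_id, doc.doc_id)
            np.testing.assert_allclose(
                store.vector(cui), raw / np.linalg.norm(raw), atol=1e-12
            )

    def test_membership_is_binary_despite_repeats(self):
        # C5 appears twice in one doc; its concept vector must count that doc once
        corpus, docs = self._toy()
        store = build_concept_vectors(corpus, docs)
        raw = docs.vector("p2", "d2") + docs.vector("p3", "d1")
        np.testing.assert_allclose(
            store.vector("C5"), raw / np.linalg.norm(raw), atol=1e-12
        )


class TestCosine:
    def test_self_cosine_is_one(self):
        v = np.array([0.3, -0.4, 1.2])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        assert cosine(np.array([1.0, 0.0, 0.0]), np.array([0.0, 2.0, 0.0])) == 0.0

    def test_hand_arithmetic(self):
        assert cosine(np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0, 1.0])) == pytest.approx(0.5)

    def test_zero_vector_defined_as_zero(self):
        assert cosine(np.zeros(3), np.array([1.0, 2.0, 3.0])) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            cosine(np.zeros(3), np.zeros(4))


class TestNearestNeighbors:
    def _store(self, n=30, dim=24, seed=0):
        rng = np.random.default_rng(seed)
        vecs = {}
        for i in range(1, n + 1):
            v = rng.normal(size=dim)
            vecs[f"C{i:03d}"] = v / np.linalg.norm(v)
        return SemanticVectorStore(vecs)

    def test_k_zero_gives_empty(self):
        store = self._store()
        assert nearest_neighbors(store, "C001", 0) == []

    def test_query_never_in_result(self):
        store = self._store()
        result = nearest_neighbors(store, "C001", len(store))
        assert "C001" not in {c for c, _ in result}

    def test_exclude_set_respected(self):
        store = self._store()
        result = nearest_neighbors(store, "C001", 10, exclude={"C002", "C003"})
        assert {"C002", "C003"}.isdisjoint({c for c, _ in result})

    def test_unknown_cui_raises(self):
        with pytest.raises(KeyError):
            nearest_neighbors(self._store(), "C999", 3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_scan(self, seed):
        store = self._store(seed=seed)
        query = "C007"
        # independent brute force: explicit cosines, same tie rule
        scored = sorted(
            (
                (c, float(np.dot(store.vector(query), store.vector(c))))
                for c in store.cuis()
                if c != query
            ),
            key=lambda t: (-t[1], t[0]),
        )
        result = nearest_neighbors(store, query, 6)
        assert [c for c, _ in result] == [c for c, _ in scored[:6]]
        np.testing.assert_allclose(
            [s for _, s in result], [s for _, s in scored[:6]], atol=1e-12
        )


class TestPipelineProperties:
    def test_determinism_bit_identical_stores(self):
        corpus = make_corpus(
            [
                ("p1", "d1", [("C1", 600), ("C2", 700)]),
                ("p2", "d1", [("C2", 800), ("C3", 900)]),
                ("p2", "d2", [("C3", 500)]),
            ]
        )
        a = build_semantic_vectors(corpus, dim=128, nonzeros=4, master_seed=9)
        b = build_semantic_vectors(corpus, dim=128, nonzeros=4, master_seed=9)
        for cui in a.cuis():
            np.testing.assert_array_equal(a.vector(cui), b.vector(cui))

    def test_second_order_association(self):
        # A and B never co-occur but both co-occur with C: their semantic
        # similarity must exceed the median similarity of A to unrelated CUIs.
        docs = [
            ("p1", "d1", [("C0000010", 500), ("C0000030", 500)]),  # A with C
            ("p2", "d1", [("C0000020", 500), ("C0000030", 500)]),  # B with C
        ]
        for i in range(1, 13):  # unrelated singleton concepts
            docs.append((f"p{i+2}", "d1", [(f"C1{i:06d}", 500)]))
        corpus = make_corpus(docs)
        store = build_semantic_vectors(corpus, dim=512, nonzeros=10, master_seed=0)
        sim_ab = cosine(store.vector("C0000010"), store.vector("C0000020"))
        unrelated = [
            cosine(store.vector("C0000010"), store.vector(f"C1{i:06d}"))
            for i in range(1, 13)
        ]
        assert sim_ab > float(np.median(unrelated))
        assert sim_ab > 0.2  # genuinely associated, not merely above noise
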