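"""Example-selection strategies: determinism, tie rules, oracle agreement."""

import numpy as np
import pytest

from cognote.corpus import NoteSection
from cognote.ensemble import PredictionSet
from cognote.fewshot import (
    DynamicKnnExamples,
    ExamplePool,
    StaticExamples,
    TfidfEmbeddingProvider,
    select_kmeans_centers,
    select_knn_dynamic,
    select_random,
    select_targeted,
)


def make_pool(n, embeddings=None, texts=None):
    sections = [
        NoteSection(f"s{i}", f"p{i}", texts[i] if texts else f"text {i}", i % 2)
        for i in range(n)
    ]
    return ExamplePool(sections=sections, embeddings=embeddings)


class FixedProvider:
    """Embedding provider backed by a lookup table keyed on text."""

    def __init__(self, table):
        self.table = table

    def embed(self, texts):
        return np.array([self.table[t] for t in texts], dtype=float)


class TestSelectRandom:
    def test_seed_reproducible_and_distinct(self):
        pool = make_pool(20)
        a = select_random(pool, 5, seed=3)
        b = select_random(pool, 5, seed=3)
        assert [s.section_id for s in a] == [s.section_id for s in b]
        assert len({s.section_id for s in a}) == 5

    def test_k_equals_pool_size(self):
        pool = make_pool(5)
        chosen = select_random(pool, 5, seed=0)
        assert {s.section_id for s in chosen} == {f"s{i}" for i in range(5)}

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            select_random(make_pool(3), 5, seed=0)

    def test_uniform_frequencies_over_seeds(self):
        """Each of 10 items is picked with frequency 5/10 ± 3 binomial sigmas
        over 10,000 seeded draws."""
        pool = make_pool(10)
        counts = np.zeros(10)
        for seed in range(10_000):
            for s in select_random(pool, 5, seed=seed):
                counts[int(s.section_id[1:])] += 1
        p = 0.5
        sigma = np.sqrt(10_000 * p * (1 - p))
        assert np.all(np.abs(counts - 5000) <= 3 * sigma)


class TestSelectTargeted:
    def _preds(self, pool, wrong_ids):
        return PredictionSet(
            "m",
            {
                s.section_id: (1 - s.label if s.section_id in wrong_ids else s.label)
                for s in pool.sections
            },
        )

    def test_exactly_k_misclassified_returns_them(self):
        pool = make_pool(10)
        wrong = {f"s{i}" for i in range(5)}
        chosen = select_targeted(pool, self._preds(pool, wrong), 5, seed=1)
        assert {s.section_id for s in chosen} == wrong

    def test_padding_with_random_correct(self):
        pool = make_pool(10)
        wrong = {"s0", "s1"}
        chosen = select_targeted(pool, self._preds(pool, wrong), 5, seed=2)
        ids = {s.section_id for s in chosen}
        assert wrong <= ids and len(ids) == 5

    def test_no_misclassifications_degenerates_to_random(self):
        pool = make_pool(10)
        chosen = select_targeted(pool, self._preds(pool, set()), 5, seed=3)
        assert len({s.section_id for s in chosen}) == 5

    def test_alignment_mismatch_rejected(self):
        pool = make_pool(4)
        with pytest.raises(ValueError, match="aligned"):
            select_targeted(pool, PredictionSet("m", {"zzz": 1}), 2, seed=0)


class TestKmeansCenters:
    def test_one_representative_per_tight_cloud(self):
        """Five well-separated 5-point clouds: brute-force expectation is one
        member from each cloud."""
        rng = np.random.default_rng(0)
        centers = np.eye(5) * 50
        X = np.vstack([c + rng.normal(0, 0.05, size=(5, 5)) for c in centers])
        pool = make_pool(25, embeddings=X)
        chosen = select_kmeans_centers(pool, 5, provider=None, seed=4)
        clouds = sorted(int(s.section_id[1:]) // 5 for s in chosen)
        assert clouds == [0, 1, 2, 3, 4]

    def test_k_equals_pool_size(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        pool = make_pool(6, embeddings=X)
        chosen = select_kmeans_centers(pool, 6, provider=None, seed=0)
        assert {s.section_id for s in chosen} == {f"s{i}" for i in range(6)}

    def test_degenerate_identical_vectors_warns_but_returns_k(self):
        X = np.ones((8, 3))
        pool = make_pool(8, embeddings=X)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            chosen = select_kmeans_centers(pool, 3, provider=None, seed=0)
        assert len({s.section_id for s in chosen}) == 3


class TestKnnDynamic:
    def test_identical_member_is_nearest(self):
        texts = ["memory loss noted", "knee pain", "routine visit"]
        pool = make_pool(3, texts=texts)
        provider = TfidfEmbeddingProvider(texts)
        query = NoteSection("q", "p", "memory loss noted", 1)
        chosen = select_knn_dynamic(query, pool, 1, provider)
        assert chosen[0].section_id == "s0"

    def test_pool_of_exactly_k(self):
        texts = ["alpha beta", "gamma delta"]
        pool = make_pool(2, texts=texts)
        provider = TfidfEmbeddingProvider(texts)
        query = NoteSection("q", "p", "alpha", 0)
        assert len(select_knn_dynamic(query, pool, 2, provider)) == 2

    def test_orthogonal_one_hots_with_tie_rule(self):
        table = {"a": [1, 0, 0], "b": [0, 1, 0], "c": [0, 0, 1], "q": [1, 0, 0]}
        pool = make_pool(3, texts=["a", "b", "c"])
        provider = FixedProvider(table)
        query = NoteSection("q", "p", "q", 0)
        chosen = select_knn_dynamic(query, pool, 2, provider)
        # axis-1 member first; the two orthogonal members tie at 0 → lowest index.
        assert [s.section_id for s in chosen] == ["s0", "s1"]

    def test_query_id_never_returned(self):
        texts = ["same text"] * 3
        pool = make_pool(3, texts=texts)
        provider = TfidfEmbeddingProvider(texts)
        query = pool.sections[1]
        chosen = select_knn_dynamic(query, pool, 2, provider)
        assert "s1" not in {s.section_id for s in chosen}

    def test_zero_vector_similarity_zero_with_warning(self):
        table = {"a": [1, 0], "b": [0, 1], "z": [0, 0]}
        pool = make_pool(2, texts=["a", "b"])
        provider = FixedProvider(table)
        query = NoteSection("q", "p", "z", 0)
        with pytest.warns(RuntimeWarning, match="zero-vector"):
            chosen = select_knn_dynamic(query, pool, 2, provider)
        assert [s.section_id for s in chosen] == ["s0", "s1"]  # all-tie → index order

    def test_agrees_with_exhaustive_similarity_sort(self, rng):
        """Exact agreement (including ties) with a brute-force oracle on
        random pools up to size 200."""
        for trial in range(10):
            n = int(rng.integers(20, 201))
            X = rng.integers(0, 3, size=(n, 8)).astype(float)  # ties likely
            q = rng.integers(0, 3, size=8).astype(float)
            texts = [f"t{trial}_{i}" for i in range(n)]
            table = {t: X[i] for i, t in enumerate(texts)}
            table["query"] = q
            pool = make_pool(n, texts=texts)
            provider = FixedProvider(table)
            query = NoteSection("q", "p", "query", 0)
            k = int(rng.integers(1, 8))
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                chosen = [s.section_id for s in select_knn_dynamic(query, pool, k, provider)]
                sims = []
                for i in range(n):
                    nx, nq = np.linalg.norm(X[i]), np.linalg.norm(q)
                    sims.append(X[i] @ q / (nx * nq) if nx > 0 and nq > 0 else 0.0)
                oracle = [f"s{i}" for i in sorted(range(n), key=lambda i: (-sims[i], i))[:k]]
            assert chosen == oracle


class TestAdapters:
    def test_static_adapter_ignores_query(self):
        adapter = StaticExamples([("a", 1), ("b", 0)])
        sec = NoteSection("q", "p", "anything", 0)
        assert adapter.select_for(sec) == [("a", 1), ("b", 0)]

    def test_dynamic_adapter_returns_k_pairs(self):
        texts = [f"word{i} filler" for i in range(10)]
        pool = make_pool(10, texts=texts)
        provider = TfidfEmbeddingProvider(texts)
        adapter = DynamicKnnExamples(pool, provider, k=5)
        sec = NoteSection("q", "p", "word3 filler", 0)
        pairs = adapter.select_for(sec)
        assert len(pairs) == 5 and pairs[0][0] == "word3 filler"
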