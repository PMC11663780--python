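"""Five-shot example selection strategies over a pluggable embedding space.

Four strategies pick the k (default 5) examples embedded into a few-shot
prompt: uniform random, targeted at previously misclassified pool members,
k-means cluster centres (one representative per cluster), and dynamic
k-nearest-neighbour retrieval recomputed per query.  The default embedding
provider is an L2-normalised TF-IDF unigram space fitted on the pool —
deterministic, local, and adequate for the lexical-similarity geometry these
strategies rely on; any provider with the same ``embed`` contract (fixed
dimension, same text → same vector) can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import Corpus, NoteSection
from .ensemble import PredictionSet

__all__ = [
    "EmbeddingProvider",
    "TfidfEmbeddingProvider",
    "ExamplePool",
    "select_random",
    "select_targeted",
    "select_kmeans_centers",
    "select_knn_dynamic",
    "StaticExamples",
    "DynamicKnnExamples",
]


class EmbeddingProvider(Protocol):
    """Deterministic text embeddings of fixed dimension."""

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


class TfidfEmbeddingProvider:
    """L2-normalised TF-IDF unigram vectors fitted on a reference pool."""

    def __init__(self, pool_texts: Sequence[str]):
        self._vectorizer = TfidfVectorizer(
            lowercase=True, token_pattern=r"[A-Za-z0-9]+", norm="l2"
        )
        self._vectorizer.fit(pool_texts)

    @property
    def dimension(self) -> int:
        return len(self._vectorizer.vocabulary_)

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.asarray(self._vectorizer.transform(texts).todense())


@dataclass
class ExamplePool:
    """Candidate example sections with an optional aligned embedding cache."""

    sections: list[NoteSection]
    embeddings: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.embeddings is not None and len(self.embeddings) != len(self.sections):
            raise ValueError(
                f"embedding cache rows ({len(self.embeddings)}) do not match "
                f"pool size ({len(self.sections)})"
            )

    def __len__(self) -> int:
        return len(self.sections)

    @classmethod
    def from_corpus(cls, corpus: Corpus, provider: EmbeddingProvider | None = None) -> "ExamplePool":
        emb = provider.embed([s.text for s in corpus.sections]) if provider else None
        return cls(sections=list(corpus.sections), embeddings=emb)

    def ensure_embeddings(self, provider: EmbeddingProvider) -> np.ndarray:
        if self.embeddings is None:
            self.embeddings = provider.embed([s.text for s in self.sections])
        return self.embeddings


def _check_pool_size(pool: ExamplePool, k: int) -> None:
    if len(pool) < k:
        raise ValueError(f"pool has {len(pool)} sections, fewer than k={k}")


def select_random(pool: ExamplePool, k: int, seed: int) -> list[NoteSection]:
    """k distinct pool members, uniform without replacement, seed-reproducible."""
    _check_pool_size(pool, k)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool.sections[i] for i in idx]


def select_targeted(
    pool: ExamplePool, prior_predictions: PredictionSet, k: int, seed: int
) -> list[NoteSection]:
    """Prefer pool members the model previously got wrong.

    Returns all misclassified members (a seeded subsample if more than k),
    padded with seeded random correctly-classified members up to k.
    """
    _check_pool_size(pool, k)
    pool_ids = {s.section_id for s in pool.sections}
    if set(prior_predictions.predictions) != pool_ids:
        raise ValueError("prior_predictions are not aligned to the pool")
    rng = np.random.default_rng(seed)
    wrong = [
        i
        for i, s in enumerate(pool.sections)
        if prior_predictions.predictions[s.section_id] != s.label
    ]
    right = [i for i in range(len(pool)) if i not in set(wrong)]
    if len(wrong) >= k:
        chosen = list(rng.choice(wrong, size=k, replace=False))
    else:
        pad = list(rng.choice(right, size=k - len(wrong), replace=False))
        chosen = wrong + pad
    return [pool.sections[int(i)] for i in chosen]


def select_kmeans_centers(
    pool: ExamplePool, k: int, provider: EmbeddingProvider, seed: int
) -> list[NoteSection]:
    """One representative per k-means cluster: the member nearest its centroid.

    Seeded k-means (10 restarts, 300-iteration cap); Euclidean nearness; ties
    and representative collisions resolved toward the lowest pool index, so
    k distinct members are always returned (with a warning when clustering is
    degenerate, e.g. all-identical vectors).
    """
    _check_pool_size(pool, k)
    X = pool.ensure_embeddings(provider)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points trigger convergence chatter
        km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed).fit(X)
    chosen: list[int] = []
    used: set[int] = set()
    degenerate = False
    for center in km.cluster_centers_:
        d = np.linalg.norm(X - center[None, :], axis=1)
        order = np.lexsort((np.arange(len(d)), d))  # distance, then lowest index
        pick = next((int(i) for i in order if int(i) not in used), None)
        if pick is None:  # pragma: no cover - impossible while len(pool) >= k
            raise RuntimeError("ran out of distinct representatives")
        if int(order[0]) in used:
            degenerate = True
        chosen.append(pick)
        used.add(pick)
    if degenerate or len(set(map(tuple, np.asarray(X)))) < k:
        warnings.warn(
            "degenerate clustering: representatives were deduplicated by pool index",
            RuntimeWarning,
            stacklevel=2,
        )
    return [pool.sections[i] for i in chosen]


def select_knn_dynamic(
    query_section: NoteSection,
    pool: ExamplePool,
    k: int,
    provider: EmbeddingProvider,
) -> list[NoteSection]:
    """The k pool members most cosine-similar to the query, recomputed per query.

    Ties break toward the lower pool index; a zero-vector embedding (query or
    member) has similarity 0 by convention, with a warning.  A pool member
    sharing the query's section id is never returned.
    """
    if not query_section.text:
        raise ValueError("query section has empty text")
    eligible = [
        i for i, s in enumerate(pool.sections) if s.section_id != query_section.section_id
    ]
    if len(eligible) < k:
        raise ValueError(f"pool has {len(eligible)} eligible sections, fewer than k={k}")
    X = pool.ensure_embeddings(provider)
    q = provider.embed([query_section.text])[0]
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(X, axis=1)
    if qn == 0 or np.any(norms[eligible] == 0):
        warnings.warn(
            "zero-vector embedding encountered; its similarity is defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = norms * qn
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = np.where(denom > 0, X @ q / np.where(denom > 0, denom, 1.0), 0.0)
    elig = np.asarray(eligible)
    order = np.lexsort((elig, -sims[elig]))  # similarity desc, then lowest index
    return [pool.sections[int(elig[i])] for i in order[:k]]


# ---------------------------------------------------------------------------
# Adapters plugging strategies into classify_sections


@dataclass
class StaticExamples:
    """A fixed example set (random / targeted / k-means strategies)."""

    examples: list[tuple[str, int]]

    @classmethod
    def from_sections(cls, sections: Sequence[NoteSection]) -> "StaticExamples":
        return cls([(s.text, s.label) for s in sections])

    def select_for(self, section: NoteSection) -> list[tuple[str, int]]:
        return self.examples


@dataclass
class DynamicKnnExamples:
    """Per-query retrieval of the k most similar pool examples."""

    pool: ExamplePool
    provider: EmbeddingProvider
    k: int = 5

    def select_for(self, section: NoteSection) -> list[tuple[str, int]]:
        chosen = select_knn_dynamic(section, self.pool, self.k, self.provider)
        return [(s.text, s.label) for s in chosen]
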