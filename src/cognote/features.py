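"""Document-term featurization for the boosted-trees baseline.

Unigram features over the shared tokenizer (split on non-alphanumerics,
lowercase), with a document-frequency floor and either raw counts or TF-IDF
weighting.  The vocabulary is sorted lexicographically and matrix rows align
to corpus section order, so featurization is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer

from .corpus import ConfigurationError, Corpus

__all__ = ["FeatureSettings", "FeatureSpace", "featurize"]

_TOKEN_PATTERN = r"[A-Za-z0-9]+"


@dataclass(frozen=True)
class FeatureSettings:
    weighting: str = "tfidf"  # "counts" or "tfidf"
    df_floor: int = 2  # minimum document frequency for a term to enter the vocabulary

    def validate(self) -> None:
        if self.weighting not in ("counts", "tfidf"):
            raise ConfigurationError(f"weighting must be 'counts' or 'tfidf', got {self.weighting!r}")
        if self.df_floor < 1:
            raise ConfigurationError("df_floor must be >= 1")


@dataclass
class FeatureSpace:
    """A fitted document-term space: vocabulary, weighting, aligned matrix."""

    vocabulary: list[str]
    weighting: str
    matrix: sp.csr_matrix
    section_ids: list[str]
    _vectorizer: object

    def transform(self, corpus: Corpus) -> sp.csr_matrix:
        """Project a new corpus onto the fitted vocabulary."""
        return self._vectorizer.transform([s.text for s in corpus.sections])


def featurize(corpus: Corpus, settings: FeatureSettings | None = None) -> FeatureSpace:
    settings = settings or FeatureSettings()
    settings.validate()
    if len(corpus) == 0:
        raise ConfigurationError("cannot featurize an empty corpus")
    cls = CountVectorizer if settings.weighting == "counts" else TfidfVectorizer
    vectorizer = cls(
        lowercase=True, token_pattern=_TOKEN_PATTERN, min_df=settings.df_floor
    )
    try:
        matrix = vectorizer.fit_transform([s.text for s in corpus.sections])
    except ValueError as exc:
        raise ConfigurationError(f"empty vocabulary after df floor {settings.df_floor}: {exc}")
    vocab = vectorizer.get_feature_names_out().tolist()  # sklearn sorts lexicographically
    return FeatureSpace(
        vocabulary=vocab,
        weighting=settings.weighting,
        matrix=matrix.tocsr(),
        section_ids=corpus.section_ids,
        _vectorizer=vectorizer,
    )
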