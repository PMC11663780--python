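"""Shared surface for the two locally trained baseline classifiers.

Both the boosted-trees model and the attention network honour a single
contract — ``fit`` on a labelled corpus, ``predict_score`` returning a
probability per section — and are thresholded at a strict 0.5 cutoff
(a score of exactly 0.5 is negative).
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .corpus import Corpus
from .ensemble import PredictionSet

from .attention_net import AttentionNetConfig, AttentionNetClassifier, train_attention_net  # noqa: F401
from .trees import DEFAULT_GRID, BoostedTreesClassifier, train_boosted_trees  # noqa: F401

__all__ = [
    "BinaryTextClassifier",
    "predict_labels",
    "cross_val_f1",
    "train_boosted_trees",
    "train_attention_net",
    "AttentionNetConfig",
    "DEFAULT_GRID",
]


class BinaryTextClassifier(Protocol):
    """Contract: scores in [0, 1], one per section, deterministic given seed."""

    def predict_score(self, corpus: Corpus) -> np.ndarray: ...


def predict_labels(
    model: BinaryTextClassifier, corpus: Corpus, cutoff: float = 0.5, model_name: str | None = None
) -> PredictionSet:
    """Threshold scores at *cutoff*: label 1 iff score > cutoff (strict)."""
    if model is None:
        raise ValueError("model is not fitted")
    scores = np.asarray(model.predict_score(corpus), dtype=float)
    if scores.shape != (len(corpus),):
        raise ValueError("model returned a score vector of the wrong length")
    name = model_name or type(model).__name__
    ids = corpus.section_ids
    return PredictionSet(
        model_name=name,
        predictions={sid: int(s > cutoff) for sid, s in zip(ids, scores)},
        scores=dict(zip(ids, scores.tolist())),
    )


def cross_val_f1(
    trainer: Callable[[Corpus], BinaryTextClassifier],
    corpus: Corpus,
    folds: int = 5,
    seed: int = 0,
    cutoff: float = 0.5,
) -> float:
    """Mean F1 over seeded stratified folds for an arbitrary trainer."""
    y = np.asarray(corpus.labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    sections = corpus.sections
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = Corpus("cv-train", [sections[i] for i in train_idx])
        test = Corpus("cv-test", [sections[i] for i in test_idx])
        model = trainer(train)
        pred = predict_labels(model, test, cutoff=cutoff)
        yhat = np.asarray(pred.labels_for(test.section_ids))
        scores.append(f1_score(y[test_idx], yhat, zero_division=0))
    return float(np.mean(scores))
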