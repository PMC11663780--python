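"""Majority-vote ensembling of binary prediction sets.

The final label is positive iff at least half-plus-one of an odd number of
models predict positive — with three models, "two or more".  Heterogeneous
models with diverse error profiles make this vote strictly better than its
inputs wherever fewer than half of them err on the same section.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import Corpus

__all__ = ["PredictionSet", "majority_vote"]


@dataclass
class PredictionSet:
    """One model's binary predictions over a corpus, keyed by section id."""

    model_name: str
    predictions: dict[str, int]
    scores: dict[str, float] | None = None
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, lab in self.predictions.items():
            if lab not in (0, 1):
                raise ValueError(
                    f"{self.model_name}: prediction for {sid!r} is {lab!r}, not 0/1"
                )

    def __len__(self) -> int:
        return len(self.predictions)

    def labels_for(self, section_ids: Sequence[str]) -> list[int]:
        return [self.predictions[sid] for sid in section_ids]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["section_id", "score", "label"])
            for sid, lab in self.predictions.items():
                score = "" if self.scores is None else f"{self.scores[sid]:.6f}"
                writer.writerow([sid, score, lab])

    @classmethod
    def from_csv(cls, path: str | Path, model_name: str | None = None) -> "PredictionSet":
        preds: dict[str, int] = {}
        scores: dict[str, float] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                preds[row["section_id"]] = int(row["label"])
                if row.get("score"):
                    scores[row["section_id"]] = float(row["score"])
        return cls(
            model_name=model_name or Path(path).stem,
            predictions=preds,
            scores=scores or None,
        )


def majority_vote(pred_sets: Sequence[PredictionSet], model_name: str = "ensemble") -> PredictionSet:
    """Combine an odd number (>= 3) of aligned prediction sets by majority.

    Raises ``ValueError`` naming the offending sets on an even count or on
    any section-id mismatch; ties are impossible by the odd-count contract.
    """
    if len(pred_sets) < 3:
        raise ValueError(f"majority vote needs >= 3 prediction sets, got {len(pred_sets)}")
    if len(pred_sets) % 2 == 0:
        names = [p.model_name for p in pred_sets]
        raise ValueError(f"majority vote needs an odd number of sets, got {len(pred_sets)}: {names}")
    ref_ids = set(pred_sets[0].predictions)
    for p in pred_sets[1:]:
        if set(p.predictions) != ref_ids:
            raise ValueError(
                f"section ids of {p.model_name!r} do not match {pred_sets[0].model_name!r}"
            )
    quorum = (len(pred_sets) + 1) // 2
    combined = {
        sid: int(sum(p.predictions[sid] for p in pred_sets) >= quorum)
        for sid in pred_sets[0].predictions
    }
    return PredictionSet(model_name=model_name, predictions=combined)


def predictions_from_labels(corpus: Corpus, model_name: str = "gold") -> PredictionSet:
    """Wrap a corpus's gold labels as a PredictionSet (alignment helper)."""
    return PredictionSet(
        model_name=model_name,
        predictions={s.section_id: s.label for s in corpus.sections},
    )
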