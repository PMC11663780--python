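"""Error-set overlap analysis for three models (the Venn machinery).

Each model's error set is the sections it mispredicts.  The three-set
decomposition stores pairwise overlaps INCLUSIVE of the triple overlap, so
inclusion–exclusion ``a+b+c−ab−ac−bc+abc`` recovers the union of errors.
The headline diversity statistic is the *mutual error fraction*: the triple
overlap as a percentage of the union (few mutual errors = diverse error
profiles = a majority vote can repair most individual mistakes).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .corpus import Corpus
from .ensemble import PredictionSet

__all__ = [
    "OverlapCounts",
    "error_sets",
    "overlap_counts",
    "inclusion_exclusion_union",
    "mutual_error_fraction",
    "plot_venn",
]


@dataclass(frozen=True)
class OverlapCounts:
    """Seven-region accounting for three error sets.

    ``ab``, ``ac``, ``bc`` are pairwise intersection sizes inclusive of the
    triple ``abc``; ``union`` counts sections missed by at least one model.
    """

    a: int
    b: int
    c: int
    ab: int
    ac: int
    bc: int
    abc: int
    union: int

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.ab, self.ac, self.bc, self.abc, self.union)
        if min(vals) < 0:
            raise ValueError("overlap counts must be non-negative")
        if self.abc > min(self.ab, self.ac, self.bc):
            raise ValueError("triple overlap exceeds a pairwise overlap")
        if self.ab > min(self.a, self.b) or self.ac > min(self.a, self.c) or self.bc > min(self.b, self.c):
            raise ValueError("a pairwise overlap exceeds one of its sets")
        expected = self.a + self.b + self.c - self.ab - self.ac - self.bc + self.abc
        if self.union != expected:
            raise ValueError(
                f"union {self.union} violates inclusion-exclusion (expected {expected})"
            )


def error_sets(pred_sets: Sequence[PredictionSet], gold: Corpus) -> dict[str, set[str]]:
    """Per model, the set of section ids where prediction != gold label."""
    gold_ids = set(gold.section_ids)
    out: dict[str, set[str]] = {}
    for pred in pred_sets:
        if set(pred.predictions) != gold_ids:
            raise ValueError(f"prediction ids of {pred.model_name!r} do not match gold")
        out[pred.model_name] = {
            s.section_id for s in gold.sections if pred.predictions[s.section_id] != s.label
        }
    return out


def overlap_counts(sets: Mapping[str, set] | Sequence[set]) -> OverlapCounts:
    """Direct set-operation decomposition of exactly three error sets."""
    values = list(sets.values()) if isinstance(sets, Mapping) else list(sets)
    if len(values) != 3:
        raise ValueError(f"overlap_counts needs exactly 3 sets, got {len(values)}")
    A, B, C = (set(v) for v in values)
    return OverlapCounts(
        a=len(A),
        b=len(B),
        c=len(C),
        ab=len(A & B),
        ac=len(A & C),
        bc=len(B & C),
        abc=len(A & B & C),
        union=len(A | B | C),
    )


def inclusion_exclusion_union(
    a: int, b: int, c: int, ab: int, ac: int, bc: int, abc: int
) -> int:
    """Union size from the seven counts (pairwise inclusive of the triple)."""
    if min(a, b, c, ab, ac, bc, abc) < 0:
        raise ValueError("counts must be non-negative")
    if abc > min(ab, ac, bc):
        raise ValueError("triple overlap exceeds a pairwise overlap")
    if ab > min(a, b) or ac > min(a, c) or bc > min(b, c):
        raise ValueError("a pairwise overlap exceeds one of its sets")
    return a + b + c - ab - ac - bc + abc


def mutual_error_fraction(counts: OverlapCounts) -> float | None:
    """100 * abc / union, rounded half-up to 1 decimal; None when union is 0."""
    if counts.union == 0:
        return None
    pct = Decimal(100 * counts.abc) / Decimal(counts.union)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def plot_venn(counts: OverlapCounts, labels: Sequence[str] = ("A", "B", "C"), path=None):
    """Draw the three-circle overlap diagram with region counts.

    Circle areas are not scaled to the counts; the figure is an annotated
    schematic.  Returns the matplotlib figure; saves to *path* if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    only_a = counts.a - counts.ab - counts.ac + counts.abc
    only_b = counts.b - counts.ab - counts.bc + counts.abc
    only_c = counts.c - counts.ac - counts.bc + counts.abc
    ab_x = counts.ab - counts.abc
    ac_x = counts.ac - counts.abc
    bc_x = counts.bc - counts.abc

    fig, ax = plt.subplots(figsize=(5, 5))
    centers = [(-0.35, 0.25), (0.35, 0.25), (0.0, -0.4)]
    for (x, y), lab in zip(centers, labels):
        ax.add_patch(Circle((x, y), 0.72, alpha=0.3, lw=1.5, ec="black"))
        ax.annotate(lab, (x, y + 0.82), ha="center", fontsize=11)
    for (x, y), v in [
        ((-0.62, 0.38), only_a),
        ((0.62, 0.38), only_b),
        ((0.0, -0.72), only_c),
        ((0.0, 0.45), ab_x),
        ((-0.38, -0.2), ac_x),
        ((0.38, -0.2), bc_x),
        ((0.0, 0.0), counts.abc),
    ]:
        ax.annotate(str(v), (x, y), ha="center", fontsize=11)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.4, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"Errors: union {counts.union}, mutual {counts.abc}")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
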