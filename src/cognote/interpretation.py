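"""Keyword-importance extraction via the mean + 2 SD selection rule.

Each model family yields an importance value per keyword — citation counts
for the prompted LLM, within-section attention weights for the attention
network, total split gain for the boosted trees — and a keyword is
*selected* when its value strictly exceeds the distribution mean plus two
sample standard deviations.  Selected keywords from all channels are merged
with the expert-curated lexicon into a single four-source report.
"""

from __future__ import annotations

import warnings
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .corpus import Corpus, KeywordLexicon

__all__ = [
    "mean2sd_select",
    "mean2sd_threshold",
    "llm_keywords",
    "attention_keywords",
    "gain_keywords",
    "merge_keyword_report",
    "render_keyword_table",
]

_COLUMNS = ["keyword", "source", "importance", "selected"]


def mean2sd_threshold(values) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("mean + 2 SD needs at least 2 values")
    return float(values.mean() + 2.0 * values.std(ddof=1))


def mean2sd_select(values) -> set[int]:
    """Indices whose value strictly exceeds mean + 2 * sample SD.

    With the sample (n-1) SD and a strict inequality, a constant vector
    selects nothing and the selection is invariant to positive rescaling.
    """
    values = np.asarray(values, dtype=float)
    threshold = mean2sd_threshold(values)
    return set(np.flatnonzero(values > threshold).tolist())


def _rows(pairs: list[tuple[str, float]], source: str) -> pd.DataFrame:
    if not pairs:
        return pd.DataFrame(columns=_COLUMNS)
    keywords = [k for k, _ in pairs]
    values = np.asarray([v for _, v in pairs], dtype=float)
    if len(values) >= 2:
        selected = np.zeros(len(values), dtype=bool)
        selected[list(mean2sd_select(values))] = True
    else:
        selected = np.zeros(len(values), dtype=bool)
    return pd.DataFrame(
        {"keyword": keywords, "source": source, "importance": values, "selected": selected}
    )


def llm_keywords(verdict_log: list[dict]) -> pd.DataFrame:
    """Keyword citation counts across all parseable verdicts, mean+2SD-selected.

    Keywords are case-folded and whitespace-trimmed before counting;
    multiword keywords are kept intact.
    """
    counts: Counter[str] = Counter()
    n_parseable = 0
    for rec in verdict_log:
        if rec.get("keywords") is None:
            continue
        n_parseable += 1
        for kw in rec["keywords"]:
            kw = " ".join(str(kw).lower().split())  # case-fold, collapse whitespace
            if kw:
                counts[kw] += 1
    if n_parseable == 0:
        warnings.warn("no parseable verdicts; LLM keyword table is empty", stacklevel=2)
        return pd.DataFrame(columns=_COLUMNS)
    if not counts:
        return pd.DataFrame(columns=_COLUMNS)
    pairs = sorted(counts.items())
    return _rows([(k, float(v)) for k, v in pairs], "llm")


def attention_keywords(model, corpus: Corpus, floor: int = 2) -> pd.DataFrame:
    """Tokens repeatedly attention-selected within individual sections.

    Per section, tokens whose attention weight strictly exceeds the
    within-section mean + 2 within-section SDs are selected; a token's
    importance is the number of sections selecting it, reported when that
    count reaches *floor*.  (The within-section rule is the published one;
    the cross-section count is this package's aggregation.)
    """
    if not hasattr(model, "attention_trace"):
        raise ValueError("model does not expose attention traces (is it fitted?)")
    section_hits: Counter[str] = Counter()
    for section in corpus.sections:
        tokens, weights = model.attention_trace(section)
        if len(tokens) < 2:
            continue
        idx = mean2sd_select(weights)
        for tok in {tokens[i] for i in idx}:
            section_hits[tok] += 1
    pairs = sorted((k, float(v)) for k, v in section_hits.items() if v >= floor)
    df = _rows(pairs, "attention_net")
    return df


def gain_keywords(boosted_model) -> pd.DataFrame:
    """Vocabulary terms whose total split gain exceeds mean + 2 SD."""
    try:
        gains = boosted_model.gain_table
    except AttributeError:
        raise ValueError("model has no gain table (train with gain recording)")
    pairs = list(zip(gains.index.tolist(), gains.to_numpy(dtype=float)))
    return _rows(pairs, "boosted_trees")


def merge_keyword_report(
    tables: list[pd.DataFrame],
    expert_lexicon: KeywordLexicon | None = None,
    selected_only: bool = True,
) -> pd.DataFrame:
    """One row per (keyword, source), expert rows always included.

    Expert-curated entries carry no importance value and are always marked
    selected; model rows keep their channel's importance.  Stable sort by
    source then keyword; the same keyword surfacing from two sources yields
    two rows.
    """
    parts = []
    if expert_lexicon is not None:
        expert = [
            e.pattern + ("-" if e.is_stem else "") for e in expert_lexicon.slice("expert")
        ]
        parts.append(
            pd.DataFrame(
                {
                    "keyword": expert,
                    "source": "expert",
                    "importance": np.nan,
                    "selected": True,
                }
            )
        )
    for t in tables:
        if len(t) == 0:
            continue
        parts.append(t[t["selected"]] if selected_only else t)
    if not parts:
        return pd.DataFrame(columns=_COLUMNS)
    merged = pd.concat(parts, ignore_index=True)[_COLUMNS]
    merged = merged.sort_values(["source", "keyword"], kind="stable").reset_index(drop=True)
    return merged


_SOURCE_TITLES = {
    "expert": "Expert Curated",
    "boosted_trees": "Boosted Trees",
    "attention_net": "Attention Network",
    "llm": "LLM",
}


def render_keyword_table(report: pd.DataFrame) -> str:
    """Render the merged report as a four-row model/keywords table."""
    lines = ["Model              | Keywords", "-" * 78]
    for source in ("expert", "boosted_trees", "attention_net", "llm"):
        rows = report[report["source"] == source]
        kws = ", ".join(rows["keyword"].tolist()) if len(rows) else "(none)"
        lines.append(f"{_SOURCE_TITLES[source]:<18} | {kws}")
    return "\n".join(lines)
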