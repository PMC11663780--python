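"""Prompt assembly, LLM backend contract, scripted test backend, and
response parsing.

A prompt is assembled from a four-part template: a required task description
(which always asks for the cognitive-decline judgment, the supporting
keywords, and JSON output), optional task guidance, an optional five-shot
examples block, and an optional paragraph of cautions distilled from a prior
error analysis.  Responses are reduced to one of three effectiveness
categories:

* ``effective_parseable`` — answers both questions in JSON;
* ``effective_unparseable`` — answers both questions, but not in JSON;
* ``not_effective`` — fails to answer either question.

The *scripted backend* is a deterministic stand-in for a hosted LLM: it
reads the target section out of the prompt, applies an expert-keyword
heuristic modulated by seeded label flips (overall and per hard-negative cue
category, so different "models" can be given distinct error profiles), and
emits a JSON verdict — or, at configured rates, a non-JSON but answer-bearing
response or a refusal.  At temperature 0 identical prompts always produce
identical responses, which is the backend contract every implementation must
honour.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .corpus import (
    ConfigurationError,
    Corpus,
    KeywordLexicon,
    NoteSection,
    load_default_lexicon,
    matched_entries,
)
from .ensemble import PredictionSet

__all__ = [
    "PromptTemplate",
    "ParsedVerdict",
    "LLMBackend",
    "ScriptedBackendConfig",
    "ScriptedBackend",
    "assemble_prompt",
    "parse_response",
    "effective_response_rate",
    "classify_sections",
    "selection_accuracy",
    "build_error_instructions",
    "default_templates",
    "template_selection_report",
]

EFFECTIVE_PARSEABLE = "effective_parseable"
EFFECTIVE_UNPARSEABLE = "effective_unparseable"
NOT_EFFECTIVE = "not_effective"

_OUTPUT_CONTRACT = (
    "Answer two questions about the target section: (1) does it show signs of "
    "cognitive decline? (2) which keywords in the text informed your judgment? "
    'Respond in JSON format: {"cognitive_decline": "yes" or "no", '
    '"keywords": [list of strings]}.'
)


@dataclass(frozen=True)
class PromptTemplate:
    """Four-part prompt template; only the task description is required."""

    template_id: str
    task_description: str
    additional_guidance: str | None = None
    few_shot_slot: bool = False
    error_instructions: str | None = None

    def __post_init__(self) -> None:
        if not self.task_description.strip():
            raise ConfigurationError(f"template {self.template_id!r}: empty task_description")


@dataclass(frozen=True)
class ParsedVerdict:
    """An LLM response reduced to category, label, and cited keywords."""

    category: str
    label: int | None
    keywords: tuple[str, ...] | None
    raw: str

    def __post_init__(self) -> None:
        parseable = self.category == EFFECTIVE_PARSEABLE
        if parseable != (self.label is not None) or parseable != (self.keywords is not None):
            raise ValueError("label/keywords present iff category is effective_parseable")

    @property
    def effective(self) -> bool:
        return self.category in (EFFECTIVE_PARSEABLE, EFFECTIVE_UNPARSEABLE)


class LLMBackend(Protocol):
    """Contract: at temperature 0, identical prompts yield identical responses."""

    name: str

    def complete(self, prompt: str, temperature: float = 0.0) -> str: ...


_TARGET_HEADER = "## Target section"
_SECTION_ID_RE = re.compile(r"\[section_id:\s*([^\]]+)\]")


def assemble_prompt(
    template: PromptTemplate,
    section: NoteSection,
    examples: Sequence[tuple[str, int]] = (),
    error_instructions: str | None = None,
) -> str:
    """Render the prompt blocks in fixed order; a pure function of its inputs.

    Order: task description → guidance → examples → error cautions → target
    section, each introduced by a labelled ``##`` header.
    """
    if examples and not template.few_shot_slot:
        raise ConfigurationError(
            f"template {template.template_id!r} has no few-shot slot but examples were supplied"
        )
    blocks = [f"## Task\n{template.task_description.strip()}\n{_OUTPUT_CONTRACT}"]
    if template.additional_guidance:
        blocks.append(f"## Guidance\n{template.additional_guidance.strip()}")
    if examples:
        lines = ["## Examples"]
        for i, (text, label) in enumerate(examples, start=1):
            verdict = "yes" if label == 1 else "no"
            lines.append(f"Example {i} (cognitive_decline: {verdict}):\n{text}")
        blocks.append("\n".join(lines))
    cautions = error_instructions or template.error_instructions
    if cautions:
        blocks.append(f"## Cautions from prior errors\n{cautions.strip()}")
    blocks.append(f"{_TARGET_HEADER}\n[section_id: {section.section_id}]\n{section.text}")
    return "\n\n".join(blocks)


# ---------------------------------------------------------------------------
# Response parsing

_YES_VALUES = {"yes", "true", "1", "y", "present", "positive"}
_NO_VALUES = {"no", "false", "0", "n", "absent", "negative"}
_JUDGMENT_KEYS = (
    "cognitive_decline",
    "cognitive decline",
    "judgment",
    "judgement",
    "decline",
    "label",
    "answer",
    "prediction",
)
_KEYWORD_KEYS = ("keywords", "keyword", "evidence", "terms")


def _normalize_label(value) -> int | None:
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, (int, float)) and value in (0, 1):
        return int(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _YES_VALUES:
            return 1
        if v in _NO_VALUES:
            return 0
    return None


def _normalize_keywords(value) -> tuple[str, ...] | None:
    if isinstance(value, str):
        value = [k for k in re.split(r"[,;]", value)]
    if isinstance(value, (list, tuple)):
        kws = tuple(str(k).strip() for k in value if str(k).strip())
        return kws  # an empty list is a valid "no keywords" answer
    return None


def _balanced_json_blocks(raw: str):
    """Yield candidate top-level ``{...}`` substrings, first to last."""
    depth = 0
    start = None
    in_str = False
    escape = False
    for i, ch in enumerate(raw):
        if in_str:
            if escape:
                escape = False
            elif ch == "\\":
                escape = True
            elif ch == '"':
                in_str = False
            continue
        if ch == '"':
            in_str = True
        elif ch == "{":
            if depth == 0:
                start = i
            depth += 1
        elif ch == "}" and depth:
            depth -= 1
            if depth == 0 and start is not None:
                yield raw[start : i + 1]
                start = None


_FREE_YES_RE = re.compile(
    r"\b(decline\s+present|cognitive\s+decline\s+(?:is\s+)?(?:present|identified)|yes)\b",
    re.IGNORECASE,
)
_FREE_NO_RE = re.compile(
    r"\b(decline\s+absent|no\s+(?:signs?\s+of\s+)?cognitive\s+decline|absent|no)\b",
    re.IGNORECASE,
)
_FREE_KEYWORDS_RE = re.compile(r"\bkeywords?\s*[:\-]", re.IGNORECASE)


def parse_response(raw: str) -> ParsedVerdict:
    """Classify any response into the three effectiveness categories.

    Never raises: a response that answers both questions in valid JSON is
    ``effective_parseable``; one that answers both in free text is
    ``effective_unparseable``; anything else is ``not_effective``.
    """
    for block in _balanced_json_blocks(raw):
        try:
            obj = json.loads(block)
        except json.JSONDecodeError:
            continue
        if not isinstance(obj, dict):
            continue
        lowered = {str(k).strip().lower(): v for k, v in obj.items()}
        label = None
        for key in _JUDGMENT_KEYS:
            if key in lowered:
                label = _normalize_label(lowered[key])
                if label is not None:
                    break
        keywords = None
        for key in _KEYWORD_KEYS:
            if key in lowered:
                keywords = _normalize_keywords(lowered[key])
                if keywords is not None:
                    break
        if label is not None and keywords is not None:
            return ParsedVerdict(EFFECTIVE_PARSEABLE, label, keywords, raw)
        break  # first JSON block is authoritative; fall back to free text
    has_judgment = bool(_FREE_YES_RE.search(raw) or _FREE_NO_RE.search(raw))
    has_keywords = bool(_FREE_KEYWORDS_RE.search(raw))
    if has_judgment and has_keywords:
        return ParsedVerdict(EFFECTIVE_UNPARSEABLE, None, None, raw)
    return ParsedVerdict(NOT_EFFECTIVE, None, None, raw)


def effective_response_rate(
    verdicts: Sequence[ParsedVerdict], count_unparseable: bool = True
) -> float:
    """Fraction of responses that answered both questions, any format."""
    if not verdicts:
        raise ValueError("effective_response_rate needs at least one verdict")
    ok = (EFFECTIVE_PARSEABLE, EFFECTIVE_UNPARSEABLE) if count_unparseable else (
        EFFECTIVE_PARSEABLE,
    )
    return sum(v.category in ok for v in verdicts) / len(verdicts)


# ---------------------------------------------------------------------------
# Scripted backend


@dataclass
class ScriptedBackendConfig:
    """Deterministic error-profile configuration for the scripted backend.

    ``flip_rate_overall`` flips the heuristic label uniformly;
    ``per_category_flip`` flips it on sections carrying a specific
    hard-negative cue category (requires ``phrase_bank`` for detection).
    ``format_break_rate`` and ``mute_rate`` emit, respectively, a non-JSON but
    answer-bearing response and a refusal.  All draws are keyed by
    (seed, section_id), so repeated calls are byte-identical.
    """

    lexicon: KeywordLexicon | None = None
    phrase_bank: "object | None" = None  # synthetic.PhraseBank, kept untyped to avoid a cycle
    flip_rate_overall: float = 0.0
    per_category_flip: Mapping[str, float] = field(default_factory=dict)
    format_break_rate: float = 0.0
    mute_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "flip_rate_overall": self.flip_rate_overall,
            "format_break_rate": self.format_break_rate,
            "mute_rate": self.mute_rate,
            **{f"per_category_flip[{k}]": v for k, v in self.per_category_flip.items()},
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {r}")


class PromptContractError(ValueError):
    """The prompt does not follow the layout produced by assemble_prompt."""


_CAUTIONS_HEADER = "## Cautions from prior errors"


class ScriptedBackend:
    """Deterministic LLM test double with a configurable error profile."""

    def __init__(self, config: ScriptedBackendConfig | None = None, name: str = "scripted"):
        self.config = config or ScriptedBackendConfig()
        self.config.validate()
        self.name = name
        self._lexicon = self.config.lexicon or load_default_lexicon()
        bank = self.config.phrase_bank
        self._positive_phrases = (
            [p for cat in bank.positive_cues.values() for p in cat] if bank else []
        )
        self._hard_neg_phrases = (
            {cat: list(ps) for cat, ps in bank.hard_negative_cues.items()} if bank else {}
        )

    def _target(self, prompt: str) -> tuple[str, str]:
        if _TARGET_HEADER not in prompt:
            raise PromptContractError("prompt has no target-section block")
        tail = prompt.rsplit(_TARGET_HEADER, 1)[1]
        m = _SECTION_ID_RE.search(tail)
        if not m:
            raise PromptContractError("target block has no [section_id: ...] line")
        section_id = m.group(1).strip()
        text = tail[m.end() :].strip()
        return section_id, text

    def _cautioned_categories(self, prompt: str) -> set[str]:
        if _CAUTIONS_HEADER not in prompt:
            return set()
        block = prompt.split(_CAUTIONS_HEADER, 1)[1].split("\n##", 1)[0].lower()
        return {cat for cat in self._hard_neg_phrases if cat in block} | {
            cat for cat in self.config.per_category_flip if cat in block
        }

    def _detect_category(self, text: str) -> str | None:
        for cat, phrases in self._hard_neg_phrases.items():
            if any(p in text for p in phrases):
                return cat
        return None

    def complete(self, prompt: str, temperature: float = 0.0) -> str:
        cfg = self.config
        section_id, text = self._target(prompt)
        rng = np.random.default_rng([cfg.seed, zlib.crc32(section_id.encode("utf-8"))])
        # Fixed draw order keeps responses stable as rates change from zero.
        u_mute, u_format, u_flip, u_cat = rng.random(4)

        matched = matched_entries(self._lexicon, text, source="expert")
        keywords = [m.rstrip("-") for m in matched]
        base = 1 if matched else 0
        category = self._detect_category(text)
        if category is not None and not any(p in text for p in self._positive_phrases):
            base = 0  # the backend "understands" non-progressive context
        flip = u_flip < cfg.flip_rate_overall
        if category is not None and category not in self._cautioned_categories(prompt):
            flip = flip or (u_cat < cfg.per_category_flip.get(category, 0.0))
        label = base ^ int(flip)

        if u_mute < cfg.mute_rate:
            return "I am unable to help with that."
        if u_format < cfg.format_break_rate:
            kw = ", ".join(keywords) if keywords else "none"
            return f"Decline {'present' if label else 'absent'}. Keywords: {kw}"
        return json.dumps(
            {"cognitive_decline": "yes" if label else "no", "keywords": keywords}
        )


# ---------------------------------------------------------------------------
# Corpus-level classification


def classify_sections(
    backend: LLMBackend,
    template: PromptTemplate,
    corpus: Corpus,
    fewshot=None,
    error_instructions: str | None = None,
    model_name: str | None = None,
) -> tuple[PredictionSet, list[dict]]:
    """Run one backend over a corpus at temperature 0.

    ``fewshot`` may be a static list of ``(text, label)`` pairs or an object
    with ``select_for(section) -> list[(text, label)]`` for per-query
    retrieval.  A non-effective or unparseable verdict is retried once
    verbatim; if still unusable, the section defaults to negative with a
    ``"fallback_negative"`` flag in the verdict log.
    """
    predictions: dict[str, int] = {}
    flags: dict[str, str] = {}
    log: list[dict] = []
    for section in corpus.sections:
        if fewshot is None:
            examples: Sequence[tuple[str, int]] = ()
        elif hasattr(fewshot, "select_for"):
            examples = fewshot.select_for(section)
        else:
            examples = fewshot
        prompt = assemble_prompt(template, section, examples, error_instructions)
        try:
            verdict = parse_response(backend.complete(prompt, temperature=0.0))
            if verdict.category != EFFECTIVE_PARSEABLE:
                verdict = parse_response(backend.complete(prompt, temperature=0.0))
        except PromptContractError:
            raise
        except Exception as exc:  # pragma: no cover - live-backend path
            raise RuntimeError(f"backend failed on section {section.section_id!r}: {exc}") from exc
        if verdict.category == EFFECTIVE_PARSEABLE:
            label = verdict.label
            flag = ""
        else:
            label = 0
            flag = "fallback_negative"
            flags[section.section_id] = flag
        predictions[section.section_id] = int(label)
        log.append(
            {
                "section_id": section.section_id,
                "category": verdict.category,
                "label": verdict.label,
                "keywords": list(verdict.keywords) if verdict.keywords is not None else None,
                "raw": verdict.raw,
                "flag": flag,
            }
        )
    name = model_name or getattr(backend, "name", "llm")
    return PredictionSet(model_name=name, predictions=predictions, flags=flags), log


def selection_accuracy(pred: PredictionSet, gold: Corpus) -> float:
    """(TP + TN) / N — the criterion used to pick a template/backend pair."""
    if set(pred.predictions) != set(gold.section_ids):
        raise ValueError("prediction and gold section ids do not match")
    correct = sum(pred.predictions[s.section_id] == s.label for s in gold.sections)
    return correct / len(gold)


# ---------------------------------------------------------------------------
# Error-analysis-based instructions

DEFAULT_CATEGORY_NOTES: dict[str, str] = {
    "improvement": (
        "Mentions of cognitive function that is improving indicate recovery, "
        "not progressive decline; label these negative."
    ),
    "transient": (
        "Temporary or occasional lapses explained by medication or fatigue "
        "are transient, not progressive decline; label these negative."
    ),
    "reversible": (
        "Confusion or impairment shortly after surgery, injury, or stroke is "
        "reversible; label these negative."
    ),
    "negated": (
        "Statements that explicitly deny memory loss or decline are negations; "
        "do not treat the mentioned terms as evidence of decline."
    ),
    "uncertain": (
        "Vague or uncertain mentions without supporting evidence do not "
        "establish progressive decline; label these negative."
    ),
    "general": "Avoid misreading signs of unrelated clinical conditions as cognitive decline.",
}


def build_error_instructions(
    error_cases: Sequence[tuple[NoteSection, int, int]],
    category_notes: Mapping[str, str] | None = None,
    phrase_bank=None,
) -> str:
    """Distil observed errors into a deterministic paragraph of cautions.

    Each error category present among *error_cases* (detected from the
    section text when a phrase bank is supplied, else ``"general"``) is
    enumerated with its note and one exemplar cue from the first offending
    section.  Output depends only on the input order.
    """
    if not error_cases:
        raise ValueError("build_error_instructions needs at least one error case")
    notes = dict(DEFAULT_CATEGORY_NOTES)
    if category_notes:
        notes.update(category_notes)
    hard_neg = (
        {cat: list(ps) for cat, ps in phrase_bank.hard_negative_cues.items()}
        if phrase_bank is not None
        else {}
    )

    def categorize(section: NoteSection) -> tuple[str, str]:
        for cat, phrases in hard_neg.items():
            for p in phrases:
                if p in section.text:
                    return cat, p
        snippet = section.text[:60].rstrip()
        return "general", snippet + ("..." if len(section.text) > 60 else "")

    seen: dict[str, str] = {}
    for section, _gold, _pred in error_cases:
        cat, exemplar = categorize(section)
        seen.setdefault(cat, exemplar)
    lines = ["The model previously made these kinds of errors; avoid repeating them:"]
    for cat, exemplar in seen.items():
        note = notes.get(cat, notes["general"])
        lines.append(f'- {cat}: {note} Example cue: "{exemplar}"')
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Template registry and selection


def default_templates() -> dict[str, PromptTemplate]:
    """A small registry of manually engineered templates.

    The iterative human paraphrasing loop is out of scope; the registry plus
    :func:`template_selection_report` reproduce its *outcome*: templates are
    ranked by effective response rate, then by selection accuracy.
    """
    task = (
        "You are reviewing one section of a clinical note. Decide whether it "
        "documents signs of cognitive decline (any stage from subjective "
        "cognitive decline through mild cognitive impairment to dementia)."
    )
    guidance_definition = (
        "Count concerns, symptoms, diagnoses, cognitive assessments, and "
        "cognition-directed therapies as evidence. Improving, transient, "
        "reversible, negated, or uncertain mentions are NOT progressive "
        "cognitive decline."
    )
    guidance_reasoning = (
        "Reason step by step about the strongest evidence before answering, "
        "but report only the final JSON object."
    )
    templates = [
        PromptTemplate("t1-task+definition", task, guidance_definition, few_shot_slot=True),
        PromptTemplate("t2-task-only", task, None, few_shot_slot=True),
        PromptTemplate("t3-task+reasoning", task, guidance_reasoning, few_shot_slot=True),
        PromptTemplate(
            "t4-task+definition+reasoning",
            task,
            guidance_definition + " " + guidance_reasoning,
            few_shot_slot=True,
        ),
    ]
    return {t.template_id: t for t in templates}


def template_selection_report(
    backend: LLMBackend,
    templates: Mapping[str, PromptTemplate],
    probe: Corpus,
    selection: Corpus,
) -> pd.DataFrame:
    """Rank templates by effective response rate on *probe*, then accuracy on
    *selection*; the first row is the chosen template."""
    rows = []
    for tid, template in templates.items():
        _, probe_log = classify_sections(backend, template, probe)
        verdicts = [
            ParsedVerdict(r["category"], r["label"], tuple(r["keywords"]) if r["keywords"] is not None else None, r["raw"])
            for r in probe_log
        ]
        err = effective_response_rate(verdicts)
        preds, _ = classify_sections(backend, template, selection)
        acc = selection_accuracy(preds, selection)
        rows.append({"template_id": tid, "effective_response_rate": err, "accuracy": acc})
    df = pd.DataFrame(rows).sort_values(
        ["effective_response_rate", "accuracy", "template_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    return df.reset_index(drop=True)
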