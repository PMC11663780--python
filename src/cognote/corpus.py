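"""Core corpus data model, readers/writers, and keyword screening.

The unit of annotation and prediction throughout the package is the *note
section*: a contiguous excerpt of a clinical note carrying a binary label
(1 = signs of cognitive decline, 0 = none).  Corpora are ordered collections
of sections with unique ids; they round-trip losslessly through JSONL and CSV.

Keyword screening mirrors the expert-curated lexicon used to enrich the
positive rate of a development corpus: entries ending in ``-`` are word-prefix
stems (``cognit-`` matches "cognitive", "cognition"), all other entries match
whole word tokens only, case-insensitively.  Multiword entries match as a
contiguous token sequence.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "NoteSection",
    "Corpus",
    "LexiconEntry",
    "KeywordLexicon",
    "CorpusFormatError",
    "ConfigurationError",
    "tokenize",
    "match_keyword",
    "keyword_filter",
    "read_corpus",
    "write_corpus",
    "load_default_lexicon",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


class CorpusFormatError(ValueError):
    """A corpus file violates the format contract (bad label, duplicate id...)."""


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the offending field."""


def tokenize(text: str) -> list[str]:
    """Split on any non-alphanumeric character and lowercase.

    Clinical punctuation is noisy, so the token stream keeps only
    alphanumeric runs; this is the single tokenizer used for keyword
    matching and featurization.
    """
    return [t.lower() for t in _TOKEN_RE.findall(text)]


@dataclass(frozen=True)
class NoteSection:
    """One labelled clinical-note section."""

    section_id: str
    patient_id: str
    text: str
    label: int

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusFormatError(f"section {self.section_id!r}: text is empty")
        if self.label not in (0, 1):
            raise CorpusFormatError(
                f"section {self.section_id!r}: label {self.label!r} not in {{0,1}}"
            )


@dataclass
class Corpus:
    """An ordered collection of note sections with unique ids."""

    name: str
    sections: list[NoteSection] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.section_id for s in self.sections]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise CorpusFormatError(f"duplicate section_id {i!r}")
                seen.add(i)

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self) -> Iterator[NoteSection]:
        return iter(self.sections)

    def __getitem__(self, idx: int) -> NoteSection:
        return self.sections[idx]

    @property
    def section_ids(self) -> list[str]:
        return [s.section_id for s in self.sections]

    @property
    def labels(self) -> list[int]:
        return [s.label for s in self.sections]

    @property
    def positive_rate(self) -> float:
        if not self.sections:
            return 0.0
        return sum(self.labels) / len(self.sections)

    def by_id(self, section_id: str) -> NoteSection:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)

    def subset(self, section_ids: Iterable[str], name: str | None = None) -> "Corpus":
        wanted = set(section_ids)
        return Corpus(
            name=name or f"{self.name}-subset",
            sections=[s for s in self.sections if s.section_id in wanted],
        )


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon pattern.

    ``is_stem`` is set when the source pattern ended with a hyphen; the
    stored pattern has the hyphen stripped.
    """

    pattern: str
    is_stem: bool
    source: str  # one of {"expert", "boosted_trees", "attention_net", "llm"}

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ConfigurationError("lexicon pattern is empty after stripping '-'")


VALID_SOURCES = ("expert", "boosted_trees", "attention_net", "llm")


@dataclass
class KeywordLexicon:
    entries: list[LexiconEntry]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.pattern.lower(), e.source)
            if key in seen:
                raise ConfigurationError(
                    f"duplicate lexicon entry ({e.pattern!r}, {e.source!r})"
                )
            seen.add(key)

    def slice(self, source: str) -> list[LexiconEntry]:
        return [e for e in self.entries if e.source == source]

    @classmethod
    def from_patterns(
        cls, patterns: Sequence[str], source: str = "expert"
    ) -> "KeywordLexicon":
        """Build a lexicon from raw patterns; trailing ``-`` marks a stem."""
        entries = []
        for p in patterns:
            p = p.strip()
            if not p:
                continue
            if p.endswith("-"):
                entries.append(LexiconEntry(p[:-1].lower(), True, source))
            else:
                entries.append(LexiconEntry(p.lower(), False, source))
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeywordLexicon":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#"):
                    continue
                pattern, source = row[0].strip(), row[1].strip()
                is_stem = pattern.endswith("-")
                entries.append(
                    LexiconEntry(pattern.rstrip("-").lower(), is_stem, source)
                )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for e in self.entries:
                writer.writerow([e.pattern + ("-" if e.is_stem else ""), e.source])


def load_default_lexicon() -> KeywordLexicon:
    """Load the packaged lexicon (expert-curated plus model-derived terms)."""
    ref = importlib.resources.files("cognote.resources").joinpath("lexicon.tsv")
    entries = []
    for line in ref.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pattern, source = line.split("\t")
        is_stem = pattern.endswith("-")
        entries.append(LexiconEntry(pattern.rstrip("-").lower(), is_stem, source))
    return KeywordLexicon(entries)


def match_keyword(entry: LexiconEntry, text: str) -> bool:
    """Case-insensitive lexicon match against a section's token stream.

    Stems match any token with the stem as a prefix; plain entries match
    whole tokens; multiword entries match a contiguous token run.
    """
    tokens = tokenize(text)
    pattern_tokens = tokenize(entry.pattern)
    if not pattern_tokens:
        return False
    if len(pattern_tokens) == 1:
        p = pattern_tokens[0]
        if entry.is_stem:
            return any(t.startswith(p) for t in tokens)
        return p in tokens
    n = len(pattern_tokens)
    for i in range(len(tokens) - n + 1):
        if tokens[i : i + n] == pattern_tokens:
            return True
    return False


def _compile_matcher(entries: Sequence[LexiconEntry]):
    """Build a single-pass matcher closure over tokenized text (fast path)."""
    whole = {e.pattern for e in entries if not e.is_stem and " " not in e.pattern}
    stems = tuple(sorted({e.pattern for e in entries if e.is_stem}))
    multi = [tuple(tokenize(e.pattern)) for e in entries if " " in e.pattern]

    def matches(text: str) -> bool:
        tokens = tokenize(text)
        tokset = set(tokens)
        if tokset & whole:
            return True
        if stems and any(t.startswith(stems) for t in tokset):
            return True
        for pat in multi:
            n = len(pat)
            for i in range(len(tokens) - n + 1):
                if tuple(tokens[i : i + n]) == pat:
                    return True
        return False

    return matches


def matched_entries(
    lexicon: KeywordLexicon, text: str, source: str = "expert"
) -> list[str]:
    """Patterns from one lexicon source that occur in *text*, in lexicon order.

    Tokenizes once and checks all entries against the shared token stream
    (equivalent to per-entry :func:`match_keyword`, but one pass).
    """
    tokens = tokenize(text)
    tokset = set(tokens)
    hits = []
    for e in lexicon.slice(source):
        pattern_tokens = tokenize(e.pattern)
        if not pattern_tokens:
            continue
        if len(pattern_tokens) == 1:
            p = pattern_tokens[0]
            ok = any(t.startswith(p) for t in tokset) if e.is_stem else p in tokset
        else:
            n = len(pattern_tokens)
            ok = any(tokens[i : i + n] == pattern_tokens for i in range(len(tokens) - n + 1))
        if ok:
            hits.append(e.pattern + ("-" if e.is_stem else ""))
    return hits


def keyword_filter(
    corpus: Corpus, lexicon: KeywordLexicon, source: str = "expert"
) -> tuple[Corpus, int]:
    """Retain sections matched by at least one lexicon entry of *source*.

    Returns the filtered corpus (order preserved, sections untouched) and the
    retention count.  This is the screening step used to enrich a development
    corpus whose raw positive rate would otherwise be too low to annotate
    efficiently.
    """
    entries = lexicon.slice(source)
    if not entries:
        raise ConfigurationError(f"lexicon has no entries with source {source!r}")
    matcher = _compile_matcher(entries)
    kept = [s for s in corpus.sections if matcher(s.text)]
    return Corpus(name=f"{corpus.name}-filtered", sections=kept), len(kept)


# ---------------------------------------------------------------------------
# Readers / writers

_COLUMNS = ("section_id", "patient_id", "text", "label")


def _section_from_record(rec: dict, lineno: int) -> NoteSection:
    for col in _COLUMNS:
        if col not in rec or rec[col] is None or rec[col] == "":
            raise CorpusFormatError(f"line {lineno}: missing column {col!r}")
    raw_label = rec["label"]
    try:
        label = int(raw_label)
    except (TypeError, ValueError):
        raise CorpusFormatError(f"line {lineno}: label {raw_label!r} is not an integer")
    if label not in (0, 1):
        raise CorpusFormatError(f"line {lineno}: label {label!r} outside {{0,1}}")
    try:
        return NoteSection(
            section_id=str(rec["section_id"]),
            patient_id=str(rec["patient_id"]),
            text=str(rec["text"]),
            label=label,
        )
    except CorpusFormatError as exc:
        raise CorpusFormatError(f"line {lineno}: {exc}") from None


def read_corpus(path: str | Path, fmt: str | None = None, name: str | None = None) -> Corpus:
    """Read a corpus from JSONL or CSV (format inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    sections: list[NoteSection] = []
    seen: set[str] = set()
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})")
                sections.append(_section_from_record(rec, lineno))
    elif fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not set(_COLUMNS) <= set(reader.fieldnames):
                missing = set(_COLUMNS) - set(reader.fieldnames or [])
                raise CorpusFormatError(f"missing column(s): {sorted(missing)}")
            for lineno, rec in enumerate(reader, start=2):
                sections.append(_section_from_record(rec, lineno))
    else:
        raise ConfigurationError(f"unknown corpus format {fmt!r}")
    for idx, s in enumerate(sections):
        if s.section_id in seen:
            raise CorpusFormatError(f"record {idx + 1}: duplicate section_id {s.section_id!r}")
        seen.add(s.section_id)
    return Corpus(name=name or path.stem, sections=sections)


def write_corpus(corpus: Corpus, path: str | Path, fmt: str | None = None) -> None:
    """Write a corpus as JSONL (default) or CSV with fixed column order."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for s in corpus.sections:
                rec = {
                    "section_id": s.section_id,
                    "patient_id": s.patient_id,
                    "text": s.text,
                    "label": s.label,
                }
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_COLUMNS))
            writer.writeheader()
            for s in corpus.sections:
                writer.writerow(
                    {
                        "section_id": s.section_id,
                        "patient_id": s.patient_id,
                        "text": s.text,
                        "label": s.label,
                    }
                )
    else:
        raise ConfigurationError(f"unknown corpus format {fmt!r}")
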