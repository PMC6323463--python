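"""Passages, tokenization, and inverted indexes for both corpora.

Source text is split into paragraph passages (blank-line delimited);
paragraphs with fewer than two sentences are dropped as likely titles
or headings.  The same record shape serves the local passage corpus and
the global document corpus, exchanged as line-delimited JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

# Terminal punctuation ends a sentence unless the preceding word is a
# known abbreviation.
_ABBREVIATIONS = frozenset(
    {"e.g", "i.e", "etc", "vs", "cf", "al", "fig", "dr", "mr", "mrs", "ms", "st"}
)
_SENT_END = re.compile(r"([.!?]+)(\s+|$)")

#: Small English stopword list used by the baseline noun-passthrough
#: stage.  Deliberately excludes the negation triggers ("no", "not",
#: "normal", "negative"), which must survive tokenization.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be been by for from had has have in into is it its of
    on or that the their then there these this to was were will with""".split()
)

_TOKEN = re.compile(r"\w+(?:-\w+)*", re.UNICODE)

# Minimal suffix stripper, used only when stemming is switched on.
_STEM_SUFFIXES = ("ing", "ed", "es", "s")


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenization options.

    Stopword removal and stemming both default to *off* so that worked
    arithmetic oracles stay exact; pass ``DEFAULT_STOPWORDS`` to enable
    the documented small English list.
    """

    stopwords: frozenset[str] = frozenset()
    stem: bool = False


DEFAULT_TOKENIZER = TokenizerConfig()


def _stem(token: str) -> str:
    for suffix in _STEM_SUFFIXES:
        if token.endswith(suffix) and len(token) > len(suffix) + 2:
            return token[: -len(suffix)]
    return token


def tokenize(text: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> list[str]:
    """Lowercase alphanumeric tokens; punctuation stripped except
    internal hyphens (so ``no-afp`` survives as one token)."""
    tokens = _TOKEN.findall(text.lower())
    if config.stopwords:
        tokens = [t for t in tokens if t not in config.stopwords]
    if config.stem:
        tokens = [_stem(t) for t in tokens]
    return tokens


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitting with an abbreviation guard list."""
    sentences: list[str] = []
    start = 0
    for match in _SENT_END.finditer(text):
        candidate = text[start : match.end(1)]
        head = candidate[: match.start(1) - start]
        last_word = head.rsplit(None, 1)[-1].lower() if head.split() else ""
        last_word = last_word.lstrip("(\"'").rstrip(".")
        if last_word in _ABBREVIATIONS:
            continue
        stripped = candidate.strip()
        if stripped:
            sentences.append(stripped)
        start = match.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


@dataclass
class Passage:
    """A paragraph-level retrieval unit (>= 2 sentences when indexed)."""

    passage_id: str
    source_id: str
    position: int
    text: str
    sentence_count: int
    links: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "passage_id": self.passage_id,
            "source_id": self.source_id,
            "position": self.position,
            "text": self.text,
            "sentence_count": self.sentence_count,
            "links": list(self.links),
        }

    @classmethod
    def from_dict(cls, rec: dict) -> "Passage":
        return cls(
            passage_id=str(rec["passage_id"]),
            source_id=str(rec.get("source_id", "")),
            position=int(rec.get("position", 0)),
            text=str(rec["text"]),
            sentence_count=int(
                rec.get("sentence_count", len(split_sentences(str(rec["text"]))))
            ),
            links=list(rec.get("links", [])),
        )


def split_passages(source_text: str, source_id: str) -> list[Passage]:
    """Split source text into passages, dropping < 2-sentence paragraphs."""
    passages: list[Passage] = []
    for block in re.split(r"\n\s*\n", source_text):
        block = block.strip()
        if not block:
            continue
        sentences = split_sentences(block)
        if len(sentences) < 2:
            continue
        position = len(passages)
        passages.append(
            Passage(
                passage_id=f"{source_id}-p{position:04d}",
                source_id=source_id,
                position=position,
                text=" ".join(sentences),
                sentence_count=len(sentences),
            )
        )
    return passages


def read_corpus(path: str | Path) -> list[Passage]:
    """Read a JSONL corpus file (one passage/document record per line)."""
    passages = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                passages.append(Passage.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: bad corpus record: {exc}") from exc
    return passages


def write_corpus(passages: Iterable[Passage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for passage in passages:
            fh.write(json.dumps(passage.to_dict(), ensure_ascii=False) + "\n")


class DuplicateUnitError(ValueError):
    pass


class InvertedIndex:
    """Term statistics over a set of retrieval units.

    Maintains postings (term -> per-unit term frequencies), document
    frequencies, unit lengths, and collection counts.  Units are stored
    in insertion order; construction is deterministic for a given input
    order.
    """

    def __init__(self) -> None:
        self.unit_ids: list[str] = []
        self._row: dict[str, int] = {}
        self._lengths: list[int] = []
        self._postings: dict[str, tuple[list[int], list[int]]] = {}
        self.total_tokens: int = 0
        self._lengths_arr: Optional[np.ndarray] = None
        self._postings_arr: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- construction ------------------------------------------------

    def add_unit(self, unit_id: str, tokens: Sequence[str]) -> None:
        if unit_id in self._row:
            raise DuplicateUnitError(f"duplicate unit id {unit_id!r}")
        row = len(self.unit_ids)
        self._row[unit_id] = row
        self.unit_ids.append(unit_id)
        self._lengths.append(len(tokens))
        self.total_tokens += len(tokens)
        counts: dict[str, int] = {}
        for tok in tokens:
            counts[tok] = counts.get(tok, 0) + 1
        for term, tf in counts.items():
            rows, tfs = self._postings.setdefault(term, ([], []))
            rows.append(row)
            tfs.append(tf)
        self._lengths_arr = None
        self._postings_arr.clear()

    # -- statistics --------------------------------------------------

    @property
    def unit_count(self) -> int:
        return len(self.unit_ids)

    @property
    def vocabulary(self) -> set[str]:
        return set(self._postings)

    def doc_freq(self, term: str) -> int:
        entry = self._postings.get(term)
        return len(entry[0]) if entry else 0

    def collection_freq(self, term: str) -> int:
        entry = self._postings.get(term)
        return sum(entry[1]) if entry else 0

    def length(self, unit_id: str) -> int:
        return self._lengths[self._row[unit_id]]

    @property
    def lengths(self) -> dict[str, int]:
        return {uid: self._lengths[i] for i, uid in enumerate(self.unit_ids)}

    @property
    def avg_length(self) -> float:
        return self.total_tokens / self.unit_count if self.unit_count else 0.0

    def postings(self, term: str) -> list[tuple[str, int]]:
        entry = self._postings.get(term)
        if not entry:
            return []
        return [(self.unit_ids[r], tf) for r, tf in zip(*entry)]

    # -- array views used by the vectorized scorers ------------------

    def lengths_array(self) -> np.ndarray:
        if self._lengths_arr is None:
            self._lengths_arr = np.asarray(self._lengths, dtype=np.float64)
        return self._lengths_arr

    def postings_arrays(self, term: str) -> tuple[np.ndarray, np.ndarray]:
        cached = self._postings_arr.get(term)
        if cached is None:
            rows, tfs = self._postings.get(term, ([], []))
            cached = (
                np.asarray(rows, dtype=np.intp),
                np.asarray(tfs, dtype=np.float64),
            )
            self._postings_arr[term] = cached
        return cached

    # -- serialization -----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "unit_ids": list(self.unit_ids),
            "lengths": list(self._lengths),
            "postings": {t: [list(rows), list(tfs)] for t, (rows, tfs) in self._postings.items()},
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "InvertedIndex":
        index = cls()
        index.unit_ids = [str(u) for u in raw["unit_ids"]]
        index._row = {uid: i for i, uid in enumerate(index.unit_ids)}
        index._lengths = [int(x) for x in raw["lengths"]]
        index.total_tokens = sum(index._lengths)
        index._postings = {
            term: ([int(r) for r in rows], [int(tf) for tf in tfs])
            for term, (rows, tfs) in raw["postings"].items()
        }
        return index

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), ensure_ascii=False), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def build_index(
    units: Iterable[Passage],
    config: TokenizerConfig = DEFAULT_TOKENIZER,
) -> InvertedIndex:
    """Index a corpus of passages/documents. Duplicate ids are an error."""
    index = InvertedIndex()
    for unit in units:
        index.add_unit(unit.passage_id, tokenize(unit.text, config))
    return index
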