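"""Weighted query representation shared across the pipeline stages.

A query evolves through translation, concept detection, synonym
expansion, negation prefixing, and feedback-based reformulation; every
stage manipulates the same term records so provenance (``origin``) and
the source concept of each term survive to the ranking stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

ORIGINS = ("original", "synonym", "prf")


@dataclass(frozen=True)
class QueryTerm:
    """One weighted query term with provenance.

    Attributes
    ----------
    term:
        Surface form used for matching index terms (already case-folded).
    weight:
        Non-negative multiplier applied to the term's score contribution.
    origin:
        ``original`` (from the user text / detected concept),
        ``synonym`` (added by synonym expansion) or ``prf`` (added by
        pseudo-relevance feedback).
    source_concept:
        Ontology instance id the term was derived from, when known.
    neg_prefixed:
        True once the ``no-`` negation prefix has been attached.
    """

    term: str
    weight: float = 1.0
    origin: str = "original"
    source_concept: Optional[str] = None
    neg_prefixed: bool = False

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown term origin {self.origin!r}")
        if not (self.weight >= 0.0 and self.weight == self.weight):
            raise ValueError(f"term weight must be finite and >= 0, got {self.weight!r}")

    def with_prefix(self) -> "QueryTerm":
        if self.neg_prefixed:
            return self
        return replace(self, term="no-" + self.term, neg_prefixed=True)


@dataclass
class WeightedQuery:
    """An ordered list of :class:`QueryTerm` records."""

    terms: list[QueryTerm] = field(default_factory=list)

    def term_strings(self) -> set[str]:
        return {t.term for t in self.terms}

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str], weight: float = 1.0) -> "WeightedQuery":
        """Build a query of ``original`` terms from plain tokens (dedup, first wins)."""
        seen: set[str] = set()
        terms = []
        for tok in tokens:
            if tok in seen:
                continue
            seen.add(tok)
            terms.append(QueryTerm(tok, weight, "original"))
        return cls(terms)
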