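"""Trigger-window negation detection and the negation query transforms.

A concept mention is *negated* when a pre-trigger token occurs within a
fixed window before its span, or a post-trigger within the window after
it, inside the same sentence; otherwise it is *affirmed*.  The default
trigger list is {"no", "not", "normal", "negative"}; "normal" and
"negative" also act as post-triggers (covering "AFP is normal",
"HIV test is negative"), "no"/"not" act before the mention.

A query is classified *abnormal* (ABN = 1) when its affirmed mentions
are at least as many as its negated ones.  For normal (negated)
concepts, synonym-expansion terms are rewritten with a "no-" prefix so
they stop matching unprefixed index terms; original terms are never
modified, preserving the query intent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from cdsearch.corpus_index import Passage, TokenizerConfig, DEFAULT_TOKENIZER, split_sentences, tokenize
from cdsearch.ontology import ConceptMention, Ontology, detect_and_translate
from cdsearch.query import WeightedQuery


@dataclass(frozen=True)
class NegationLexicon:
    pre_triggers: frozenset[str] = frozenset({"no", "not", "normal", "negative"})
    post_triggers: frozenset[str] = frozenset({"normal", "negative"})
    window: int = 5

    def __post_init__(self) -> None:
        if not self.pre_triggers or not self.post_triggers:
            raise ValueError("trigger sets must be non-empty")
        if self.window < 1:
            raise ValueError("window must be >= 1")


DEFAULT_NEGATION = NegationLexicon()


@dataclass
class NegationProfile:
    """Mention polarity tallies; ``abn`` is set for queries only."""

    affirmed_count: int = 0
    negated_count: int = 0
    abn: Optional[int] = None


def detect_polarity(
    tokens: Sequence[str],
    mentions: Iterable[ConceptMention],
    lexicon: NegationLexicon = DEFAULT_NEGATION,
    sentence_bounds: Optional[Sequence[tuple[int, int]]] = None,
) -> list[ConceptMention]:
    """Assign affirmed/negated polarity to each mention.

    ``sentence_bounds`` is a list of half-open token spans, one per
    sentence; trigger scanning never crosses them.  When omitted the
    whole sequence is treated as one sentence.
    """
    n = len(tokens)
    if sentence_bounds is None:
        sentence_bounds = [(0, n)]
    out: list[ConceptMention] = []
    for mention in mentions:
        start, end = mention.span
        if start < 0 or end > n:
            raise ValueError(
                f"mention {mention.representative_term!r} span {mention.span} "
                f"out of range for {n} tokens"
            )
        sent = next(((s, e) for s, e in sentence_bounds if s <= start < e), (0, n))
        pre = tokens[max(sent[0], start - lexicon.window) : start]
        post = tokens[end : min(sent[1], end + lexicon.window)]
        negated = any(t in lexicon.pre_triggers for t in pre) or any(
            t in lexicon.post_triggers for t in post
        )
        out.append(
            ConceptMention(
                instance_id=mention.instance_id,
                surface=mention.surface,
                representative_term=mention.representative_term,
                span=mention.span,
                polarity="negated" if negated else "affirmed",
            )
        )
    return out


def apply_no_prefix(
    query: WeightedQuery,
    mentions: Iterable[ConceptMention],
) -> WeightedQuery:
    """Prefix synonym-origin terms of negated concepts with ``no-``.

    Original and PRF-origin terms are never modified; the transform is
    idempotent.
    """
    negated_ids = {m.instance_id for m in mentions if m.polarity == "negated"}
    new_terms = []
    for term in query.terms:
        if (
            term.origin == "synonym"
            and term.source_concept in negated_ids
            and not term.neg_prefixed
        ):
            new_terms.append(term.with_prefix())
        else:
            new_terms.append(term)
    return WeightedQuery(new_terms)


def query_abnormality(mentions: Iterable[ConceptMention]) -> NegationProfile:
    """Tally query mention polarity; ABN = 1 iff affirmed >= negated.

    A concept-free query yields (0, 0) and hence ABN = 1 (the inclusive
    comparison applied literally).
    """
    affirmed = negated = 0
    for mention in mentions:
        if mention.polarity == "affirmed":
            affirmed += 1
        elif mention.polarity == "negated":
            negated += 1
        else:
            raise ValueError(
                f"mention {mention.representative_term!r} has unassessed polarity"
            )
    return NegationProfile(
        affirmed_count=affirmed,
        negated_count=negated,
        abn=1 if affirmed >= negated else 0,
    )


def analyze_text(
    text: str,
    ontology: Ontology,
    lexicon: NegationLexicon = DEFAULT_NEGATION,
    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER,
    max_ngram: int = 4,
) -> tuple[list[str], list[tuple[int, int]], list[ConceptMention]]:
    """Tokenize sentence-wise, detect concepts, and assign polarity.

    Returns the flat token sequence, the per-sentence token bounds, and
    the polarity-annotated mentions.
    """
    tokens: list[str] = []
    bounds: list[tuple[int, int]] = []
    for sentence in split_sentences(text):
        sent_tokens = tokenize(sentence, tokenizer)
        bounds.append((len(tokens), len(tokens) + len(sent_tokens)))
        tokens.extend(sent_tokens)
    mentions = detect_and_translate(tokens, ontology, max_ngram=max_ngram)
    mentions = detect_polarity(tokens, mentions, lexicon, bounds)
    return tokens, bounds, mentions


def passage_polarity_counts(
    passage: Passage,
    ontology: Ontology,
    lexicon: NegationLexicon = DEFAULT_NEGATION,
    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER,
) -> NegationProfile:
    """Count affirmed/negated concept mentions in a passage.

    Repeated concepts count once per mention; ``abn`` stays unset for
    passages.
    """
    _, _, mentions = analyze_text(passage.text, ontology, lexicon, tokenizer)
    affirmed = sum(1 for m in mentions if m.polarity == "affirmed")
    negated = sum(1 for m in mentions if m.polarity == "negated")
    return NegationProfile(affirmed_count=affirmed, negated_count=negated)
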