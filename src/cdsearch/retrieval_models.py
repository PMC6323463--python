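"""TF-IDF, BM25 and Dirichlet language-model scoring of weighted queries.

Formula variants (the variant tag of each is recorded in run metadata):

* ``tfidf``: sum over matched terms of ``w_t * (1 + ln tf) * log10(N / df_t)``.
* ``bm25``: Robertson tf saturation with the non-negative (Lucene-style)
  idf ``ln(1 + (N - df + 0.5) / (df + 0.5))``; ``k1 = 1.2``, ``b = 0.75``.
* ``lm``: Dirichlet-smoothed query log-likelihood with ``mu = 2500``;
  defined for every unit (scores <= 0); query terms absent from the
  collection are skipped (their smoothed probability is undefined).

Query weights multiply each term's score contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from cdsearch.corpus_index import InvertedIndex
from cdsearch.query import QueryTerm, WeightedQuery

__all__ = [
    "ModelParams",
    "WeightedQuery",
    "QueryTerm",
    "MODELS",
    "score_passages",
    "retrieve_topk",
]

MODELS = ("tfidf", "bm25", "lm")


@dataclass(frozen=True)
class ModelParams:
    mu: float = 2500.0
    bm25_k1: float = 1.2
    bm25_b: float = 0.75
    tfidf_variant: str = "lntf.log10idf"

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if not 0.0 <= self.bm25_b <= 1.0:
            raise ValueError("bm25_b must be in [0, 1]")
        if self.bm25_k1 < 0:
            raise ValueError("bm25_k1 must be >= 0")

    def variant_tags(self) -> dict[str, str]:
        """Formula variant tags for run metadata."""
        return {
            "tfidf": self.tfidf_variant,
            "bm25": f"lucene-idf,k1={self.bm25_k1},b={self.bm25_b}",
            "lm": f"dirichlet,mu={self.mu}",
        }


DEFAULT_PARAMS = ModelParams()


def _score_array(
    query: WeightedQuery,
    index: InvertedIndex,
    model: str,
    params: ModelParams,
) -> np.ndarray:
    n = index.unit_count
    scores = np.zeros(n, dtype=np.float64)
    if model == "tfidf":
        for term in query.terms:
            df = index.doc_freq(term.term)
            if df == 0 or term.weight == 0:
                continue
            rows, tfs = index.postings_arrays(term.term)
            idf = math.log10(n / df)
            scores[rows] += term.weight * (1.0 + np.log(tfs)) * idf
    elif model == "bm25":
        lengths = index.lengths_array()
        avg = index.avg_length
        k1, b = params.bm25_k1, params.bm25_b
        for term in query.terms:
            df = index.doc_freq(term.term)
            if df == 0 or term.weight == 0:
                continue
            rows, tfs = index.postings_arrays(term.term)
            idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
            denom = tfs + k1 * (1.0 - b + b * lengths[rows] / avg)
            scores[rows] += term.weight * idf * tfs * (k1 + 1.0) / denom
    elif model == "lm":
        lengths = index.lengths_array()
        mu = params.mu
        total_weight = 0.0
        log_len = np.log(lengths + mu)
        for term in query.terms:
            cf = index.collection_freq(term.term)
            if cf == 0 or term.weight == 0:
                continue
            p_coll = cf / index.total_tokens
            base = math.log(mu * p_coll)
            scores += term.weight * base
            rows, tfs = index.postings_arrays(term.term)
            if rows.size:
                scores[rows] += term.weight * (np.log(tfs + mu * p_coll) - base)
            total_weight += term.weight
        scores -= total_weight * log_len
    else:
        raise ValueError(f"unknown retrieval model {model!r}")
    return scores


def score_passages(
    query: WeightedQuery,
    index: InvertedIndex,
    model: str,
    params: ModelParams = DEFAULT_PARAMS,
) -> dict[str, float]:
    """Score every indexed unit for the weighted query.

    Under ``tfidf``/``bm25`` units sharing no term with the query score
    exactly 0; under ``lm`` every unit receives a (<= 0) log-likelihood.
    """
    if index.unit_count == 0:
        raise ValueError("cannot score against an empty index")
    scores = _score_array(query, index, model, params)
    return dict(zip(index.unit_ids, scores.tolist()))


def retrieve_topk(
    scores: dict[str, float],
    k: int,
    positive_only: bool = False,
) -> list[tuple[str, float]]:
    """Top-k units, descending score, ties broken by ascending unit id.

    With ``positive_only`` (the tfidf/bm25 convention) only units with
    score > 0 are eligible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = scores.items()
    if positive_only:
        items = [(u, s) for u, s in items if s > 0]
    ranked = sorted(items, key=lambda item: (-item[1], item[0]))
    return ranked[:k]
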