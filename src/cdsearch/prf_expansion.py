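"""Multilevel pseudo-relevance feedback term weighting and reformulation.

Given the top-k feedback units for a query, every term in the root set
(query terms plus all feedback-unit terms) receives a raw weight

    S_t(t) = alpha * I_Q(t) * tf_t / N  +  (beta / k) * sum_i I_Pi(t) * ipf_t

damped to ``S = log10(10 + S_t)`` (so S(0) = 1), where ``tf_t`` counts
the term in the concatenated feedback units, ``N`` is their total token
count, ``I_Q``/``I_Pi`` are query/unit membership indicators, and
``ipf_t = log10((k + 1) / pf_t)`` is the inverse unit frequency over
the feedback set.  Tables from the local (passage) and global
(document) corpora are fused convexly with mixing factor ``lam``; the
top-m fused terms not already in the query are appended with weights
max-normalized into (0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from cdsearch.query import QueryTerm, WeightedQuery

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRFConfig:
    alpha: float = 2.0
    beta: float = 0.75
    k: int = 5
    lam: float = 0.65
    m: int = 35

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


DEFAULT_PRF = PRFConfig()

#: Damped weight assigned to a term absent from a table (S_t = 0).
DEGENERATE_WEIGHT = 1.0


@dataclass
class TermWeight:
    """Per-term feedback statistics and weights."""

    term: str
    tf: int = 0
    pf: int = 0
    in_query: bool = False
    ipf: float = 0.0
    s_raw: float = 0.0
    s_damped: float = DEGENERATE_WEIGHT
    s_prf: Optional[float] = None


@dataclass
class TermWeightTable:
    """Weight records for one query over one feedback corpus."""

    records: dict[str, TermWeight] = field(default_factory=dict)
    n_tokens: int = 0
    k_used: int = 0

    def damped(self, term: str) -> float:
        rec = self.records.get(term)
        return rec.s_damped if rec is not None else DEGENERATE_WEIGHT

    def fused(self, term: str) -> float:
        rec = self.records.get(term)
        if rec is None:
            return DEGENERATE_WEIGHT
        return rec.s_prf if rec.s_prf is not None else rec.s_damped

    def __len__(self) -> int:
        return len(self.records)


def prf_term_weights(
    query: WeightedQuery,
    feedback_units: Sequence[Sequence[str]],
    config: PRFConfig = DEFAULT_PRF,
) -> TermWeightTable:
    """Weight every root-set term from the top-k feedback units.

    ``feedback_units`` are the token sequences of the top-k retrieved
    units (possibly fewer when the corpus is small).  With an empty
    feedback set the table degenerates to query terms at S = 1.
    """
    query_terms = query.term_strings()
    k_used = len(feedback_units)
    table = TermWeightTable(k_used=k_used)

    tf: dict[str, int] = {}
    pf: dict[str, int] = {}
    n_tokens = 0
    for unit in feedback_units:
        seen: set[str] = set()
        for tok in unit:
            tf[tok] = tf.get(tok, 0) + 1
            seen.add(tok)
        for tok in seen:
            pf[tok] = pf.get(tok, 0) + 1
        n_tokens += len(unit)
    table.n_tokens = n_tokens

    if k_used == 0 or n_tokens == 0:
        logger.warning("empty feedback set; PRF table degenerates to query terms at S=1")
        for term in sorted(query_terms):
            table.records[term] = TermWeight(term=term, in_query=True)
        return table

    root = set(tf) | query_terms
    for term in sorted(root):
        term_tf = tf.get(term, 0)
        term_pf = pf.get(term, 0)
        ipf = math.log10((k_used + 1) / term_pf) if term_pf > 0 else 0.0
        in_query = term in query_terms
        s_raw = (
            config.alpha * (1.0 if in_query else 0.0) * term_tf / n_tokens
            + (config.beta / k_used) * term_pf * ipf
        )
        table.records[term] = TermWeight(
            term=term,
            tf=term_tf,
            pf=term_pf,
            in_query=in_query,
            ipf=ipf,
            s_raw=s_raw,
            s_damped=math.log10(10.0 + s_raw),
        )
    return table


def fuse_prf(
    local: TermWeightTable,
    global_: TermWeightTable,
    config: PRFConfig = DEFAULT_PRF,
) -> TermWeightTable:
    """Convex fusion ``S_prf = lam * S_local + (1 - lam) * S_global``.

    Total over the union of both tables; a term missing from one side
    contributes that side's degenerate value 1 (i.e. S_t = 0).
    """
    fused = TermWeightTable(n_tokens=local.n_tokens, k_used=local.k_used)
    for term in sorted(set(local.records) | set(global_.records)):
        s_l = local.damped(term)
        s_g = global_.damped(term)
        base = local.records.get(term) or global_.records.get(term) or TermWeight(term=term)
        fused.records[term] = replace(
            base, s_prf=config.lam * s_l + (1.0 - config.lam) * s_g
        )
    return fused


def expand_query(
    query: WeightedQuery,
    fused: TermWeightTable,
    config: PRFConfig = DEFAULT_PRF,
) -> WeightedQuery:
    """Append the top-m fused terms not already in the query.

    Candidates are ranked by fused weight descending (ties by ascending
    term string); the appended terms carry origin ``prf`` and weights
    normalized by the maximum fused weight among them, so added weights
    lie in (0, 1].
    """
    existing = query.term_strings()
    candidates = [
        (rec.term, fused.fused(rec.term))
        for rec in fused.records.values()
        if rec.term not in existing
    ]
    if config.m == 0 or not candidates:
        return WeightedQuery(list(query.terms))
    candidates.sort(key=lambda item: (-item[1], item[0]))
    chosen = candidates[: config.m]
    max_weight = chosen[0][1]
    scale = 1.0 / max_weight if max_weight > 0 else 0.0
    new_terms = list(query.terms)
    for term, weight in chosen:
        new_terms.append(QueryTerm(term, weight * scale, "prf"))
    return WeightedQuery(new_terms)
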