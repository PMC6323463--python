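"""End-to-end retrieval pipeline and the five named configurations.

Stage order for a query: tokenize -> concept detection/translation (or
noun-like passthrough for the baseline) -> synonym expansion -> polarity
detection and "no-" prefixing -> local feedback on the passage index ->
global feedback on the document index -> convex fusion of the two
weight tables -> top-m reformulation -> three-model scoring ->
normalized score fusion -> abnormality boost -> final ranking.  Each
stage is toggled by configuration flags whose allowed combinations
follow the nested feature ladder baseline ⊂ UMLSE ⊂ LPRF ⊂ GPRF ⊂
GPRF-NEG (plus a free "custom" mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from cdsearch.corpus_index import (
    DEFAULT_STOPWORDS,
    DEFAULT_TOKENIZER,
    InvertedIndex,
    Passage,
    TokenizerConfig,
    build_index,
    tokenize,
)
from cdsearch.evaluation import Judgments, RunRecord, evaluate_runs, per_query_metric
from cdsearch.negation import (
    DEFAULT_NEGATION,
    NegationLexicon,
    NegationProfile,
    analyze_text,
    apply_no_prefix,
    passage_polarity_counts,
    query_abnormality,
)
from cdsearch.ontology import (
    Ontology,
    OntologySynonymProvider,
    expand_synonyms,
)
from cdsearch.prf_expansion import (
    DEFAULT_PRF,
    PRFConfig,
    TermWeightTable,
    expand_query,
    fuse_prf,
    prf_term_weights,
)
from cdsearch.query import QueryTerm, WeightedQuery
from cdsearch.ranking import (
    DEFAULT_FUSION,
    FusionConfig,
    negation_boost,
    normalize_and_fuse,
    rank_final,
)
from cdsearch.retrieval_models import (
    DEFAULT_PARAMS,
    MODELS,
    ModelParams,
    score_passages,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    name: str = "custom"
    use_ontology_cd: bool = True
    use_synonym_expansion: bool = True
    use_local_prf: bool = True
    use_global_prf: bool = True
    use_negation: bool = True
    synonym_weight: float = 0.5
    max_ngram: int = 4
    model_params: ModelParams = DEFAULT_PARAMS
    prf: PRFConfig = DEFAULT_PRF
    fusion: FusionConfig = DEFAULT_FUSION
    negation_lexicon: NegationLexicon = DEFAULT_NEGATION
    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER

    def __post_init__(self) -> None:
        if self.use_global_prf and not self.use_local_prf:
            raise ValueError("global PRF requires local PRF (feature nesting)")
        if self.use_negation and not self.use_global_prf:
            raise ValueError("negation re-ranking requires global PRF (feature nesting)")

    def metadata(self) -> dict:
        """Run metadata: flags and formula variant tags."""
        return {
            "config": self.name,
            "flags": {
                "use_ontology_cd": self.use_ontology_cd,
                "use_synonym_expansion": self.use_synonym_expansion,
                "use_local_prf": self.use_local_prf,
                "use_global_prf": self.use_global_prf,
                "use_negation": self.use_negation,
            },
            "model_variants": self.model_params.variant_tags(),
            "prf": {
                "alpha": self.prf.alpha,
                "beta": self.prf.beta,
                "k": self.prf.k,
                "lambda": self.prf.lam,
                "m": self.prf.m,
            },
            "fusion": {
                "n_models": self.fusion.n_models,
                "pool_size": self.fusion.m_retrieved,
                "gamma": self.fusion.gamma,
                "depth": self.fusion.output_depth,
                "eq4_denominator": "pooled-total",
            },
        }


#: The five compared configurations (nested feature ladder).
NAMED_CONFIGS: dict[str, PipelineConfig] = {
    "baseline": PipelineConfig(
        name="baseline",
        use_ontology_cd=False,
        use_synonym_expansion=False,
        use_local_prf=False,
        use_global_prf=False,
        use_negation=False,
    ),
    "umlse": PipelineConfig(
        name="umlse",
        use_ontology_cd=True,
        use_synonym_expansion=True,
        use_local_prf=False,
        use_global_prf=False,
        use_negation=False,
    ),
    "lprf": PipelineConfig(
        name="lprf",
        use_ontology_cd=True,
        use_synonym_expansion=True,
        use_local_prf=True,
        use_global_prf=False,
        use_negation=False,
    ),
    "gprf": PipelineConfig(
        name="gprf",
        use_ontology_cd=True,
        use_synonym_expansion=True,
        use_local_prf=True,
        use_global_prf=True,
        use_negation=False,
    ),
    "gprf-neg": PipelineConfig(
        name="gprf-neg",
        use_ontology_cd=True,
        use_synonym_expansion=True,
        use_local_prf=True,
        use_global_prf=True,
        use_negation=True,
    ),
}


def named_config(name: str, **overrides) -> PipelineConfig:
    try:
        config = NAMED_CONFIGS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown configuration {name!r}; choose from {sorted(NAMED_CONFIGS)}"
        ) from None
    return replace(config, **overrides) if overrides else config


class SearchEngine:
    """Holds the ontology and both indexes; executes pipeline searches."""

    def __init__(
        self,
        ontology: Ontology,
        passages: Sequence[Passage],
        documents: Sequence[Passage] = (),
        tokenizer: TokenizerConfig = DEFAULT_TOKENIZER,
    ) -> None:
        self.ontology = ontology
        self.tokenizer = tokenizer
        self.passages = list(passages)
        self.documents = list(documents)
        self.passage_index: InvertedIndex = build_index(self.passages, tokenizer)
        self.doc_index: Optional[InvertedIndex] = (
            build_index(self.documents, tokenizer) if self.documents else None
        )
        self._passage_tokens = {
            p.passage_id: tokenize(p.text, tokenizer) for p in self.passages
        }
        self._doc_tokens = {
            d.passage_id: tokenize(d.text, tokenizer) for d in self.documents
        }
        self._provider = OntologySynonymProvider(ontology)
        self._profiles: Optional[dict[str, NegationProfile]] = None

    # -- cached per-passage polarity profiles ------------------------

    def passage_profiles(
        self, lexicon: NegationLexicon = DEFAULT_NEGATION
    ) -> dict[str, NegationProfile]:
        if self._profiles is None:
            self._profiles = {
                p.passage_id: passage_polarity_counts(
                    p, self.ontology, lexicon, self.tokenizer
                )
                for p in self.passages
            }
        return self._profiles

    # -- internal stages ---------------------------------------------

    def _score_all_models(
        self, query: WeightedQuery, index: InvertedIndex, config: PipelineConfig
    ) -> dict[str, dict[str, float]]:
        return {
            model: score_passages(query, index, model, config.model_params)
            for model in MODELS
        }

    def _feedback_table(
        self,
        query: WeightedQuery,
        index: InvertedIndex,
        token_map: Mapping[str, list[str]],
        config: PipelineConfig,
    ) -> TermWeightTable:
        scores = self._score_all_models(query, index, config)
        fused = normalize_and_fuse(scores, config.fusion)
        top = sorted(fused.items(), key=lambda item: (-item[1], item[0]))[: config.prf.k]
        units = [token_map[uid] for uid, _ in top]
        return prf_term_weights(query, units, config.prf)

    # -- the pipeline -------------------------------------------------

    def reformulate(
        self,
        query_text: str,
        config: PipelineConfig,
        trace: Optional[dict] = None,
    ) -> tuple[WeightedQuery, Optional[NegationProfile]]:
        """Run every query-side stage (through PRF reformulation).

        Returns the final weighted query and, when negation is enabled,
        the query's polarity profile.
        """
        tokens, bounds, mentions = analyze_text(
            query_text,
            self.ontology,
            config.negation_lexicon,
            self.tokenizer,
            config.max_ngram,
        )

        query_profile: Optional[NegationProfile] = None
        if config.use_ontology_cd and mentions:
            if config.use_synonym_expansion:
                terms = expand_synonyms(mentions, self._provider, config.synonym_weight)
            else:
                terms = []
                seen: set[str] = set()
                for m in mentions:
                    if m.representative_term not in seen:
                        seen.add(m.representative_term)
                        terms.append(
                            QueryTerm(m.representative_term, 1.0, "original", m.instance_id)
                        )
            query = WeightedQuery(terms)
        else:
            if config.use_ontology_cd:
                logger.warning(
                    "no concepts detected in %r; falling back to raw tokens", query_text
                )
            # noun-like passthrough: stopword-filtered raw tokens
            query = WeightedQuery.from_tokens(
                t for t in tokens if t not in DEFAULT_STOPWORDS
            )

        if config.use_negation:
            query_profile = query_abnormality(mentions)
            query = apply_no_prefix(query, mentions)

        self._trace(trace, "query_representation", query)

        if config.use_local_prf and len(query):
            local = self._feedback_table(
                query, self.passage_index, self._passage_tokens, config
            )
            if config.use_global_prf and self.doc_index is not None:
                global_ = self._feedback_table(
                    query, self.doc_index, self._doc_tokens, config
                )
                fused_table = fuse_prf(local, global_, config.prf)
            else:
                # local-only: fuse against an empty table at lam = 1
                fused_table = fuse_prf(local, TermWeightTable(), replace(config.prf, lam=1.0))
            query = expand_query(query, fused_table, config.prf)
            self._trace(trace, "expanded_query", query)

        return query, query_profile

    def run_search(
        self,
        query_text: str,
        config: PipelineConfig,
        trace: Optional[dict] = None,
    ) -> list[tuple[str, float]]:
        """Execute the full pipeline for one query text.

        Pass a dict as ``trace`` to capture per-stage intermediate
        state (term counts and top weighted terms).
        """
        query, query_profile = self.reformulate(query_text, config, trace)
        if not len(query):
            return []

        per_model = self._score_all_models(query, self.passage_index, config)
        fused_scores = normalize_and_fuse(per_model, config.fusion)
        if config.use_negation and query_profile is not None:
            profiles = self.passage_profiles(config.negation_lexicon)
            fused_scores = negation_boost(
                fused_scores, profiles, query_profile, config.fusion
            )
        ranked = rank_final(fused_scores, config.fusion)
        if trace is not None:
            trace["query_profile"] = query_profile
            trace["final_depth"] = len(ranked)
        return ranked

    @staticmethod
    def _trace(trace: Optional[dict], stage: str, query: WeightedQuery) -> None:
        if trace is None:
            return
        top = sorted(query.terms, key=lambda t: -t.weight)[:5]
        trace[stage] = {
            "n_terms": len(query),
            "top_terms": [(t.term, round(t.weight, 4), t.origin) for t in top],
        }
        logger.debug("%s: %s", stage, trace[stage])

    def run_batch(
        self,
        queries: Sequence,
        config: PipelineConfig,
    ) -> dict[str, RunRecord]:
        """Run every query; returns TREC-style run records keyed by qid.

        ``queries`` holds objects with ``query_id`` and ``text``
        attributes (e.g. :class:`cdsearch.synthetic_fixtures.Query`).
        """
        runs = {}
        for q in queries:
            ranked = self.run_search(q.text, config)
            runs[q.query_id] = RunRecord(
                query_id=q.query_id,
                entries=ranked[: config.fusion.output_depth],
                tag=config.name,
            )
        return runs


def evaluate_run(
    runs: Mapping[str, RunRecord],
    judgments: Judgments,
    metrics: Sequence[str] = ("p5", "rprec", "ndcg10", "mrr"),
) -> dict[str, dict[str, float]]:
    """Per-query and mean metrics for a run, warning on orphan queries."""
    orphans = sorted(set(runs) - set(judgments.query_ids()))
    if orphans:
        logger.warning("queries without judgments: %s", ", ".join(orphans))
    return evaluate_runs(runs, judgments, metrics)


__all__ = [
    "PipelineConfig",
    "NAMED_CONFIGS",
    "named_config",
    "SearchEngine",
    "evaluate_run",
    "per_query_metric",
]
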