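"""Multi-model score fusion and the negation-differential boost.

Fusion: the candidate pool is the union of each model's top-M units.
Per model, scores are min-max normalized over the pool (units a model
did not score are imputed with that model's pool minimum, so absence is
never rewarded; a degenerate model with max = min contributes 0 for all
units).  The fused score of a unit is its summed normalized score
divided by the pool total, so fused scores form a distribution summing
to 1 over the pool.

Boost: for an abnormal query (ABN = 1) each unit's fused score gains
``gamma * (1 + AFFIRMED / (AFFIRMED + NEGATED))``, with the fraction 0
for mention-free units; ABN = 0 leaves scores untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from cdsearch.negation import NegationProfile
from cdsearch.retrieval_models import retrieve_topk

POSITIVE_ONLY_MODELS = frozenset({"tfidf", "bm25"})


@dataclass(frozen=True)
class FusionConfig:
    n_models: int = 3
    m_retrieved: int = 100
    gamma: float = 2.0
    output_depth: int = 500

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.m_retrieved < 1:
            raise ValueError("m_retrieved must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


DEFAULT_FUSION = FusionConfig()


def normalize_and_fuse(
    per_model_scores: Mapping[str, Mapping[str, float]],
    config: FusionConfig = DEFAULT_FUSION,
) -> dict[str, float]:
    """Min-max normalize each model over the pooled top-M and fuse.

    Returns a mapping over the pool whose values sum to 1 (uniform when
    every model is degenerate).  An empty pool yields an empty mapping.
    """
    pool: set[str] = set()
    for model, scores in per_model_scores.items():
        if not scores:
            continue
        top = retrieve_topk(
            dict(scores), config.m_retrieved, positive_only=model in POSITIVE_ONLY_MODELS
        )
        pool.update(uid for uid, _ in top)
    if not pool:
        return {}
    pool_ids = sorted(pool)
    fused = {uid: 0.0 for uid in pool_ids}
    for model, scores in per_model_scores.items():
        present = [scores[uid] for uid in pool_ids if uid in scores]
        if not present:
            continue
        floor = min(present)
        vals = {uid: scores.get(uid, floor) for uid in pool_ids}
        lo, hi = min(vals.values()), max(vals.values())
        if hi == lo:
            continue  # degenerate model contributes 0 everywhere
        span = hi - lo
        for uid in pool_ids:
            fused[uid] += (vals[uid] - lo) / span
    total = sum(fused.values())
    if total == 0.0:
        uniform = 1.0 / len(pool_ids)
        return {uid: uniform for uid in pool_ids}
    return {uid: score / total for uid, score in fused.items()}


def negation_boost(
    fused: Mapping[str, float],
    profiles: Mapping[str, NegationProfile],
    query_profile: NegationProfile,
    config: FusionConfig = DEFAULT_FUSION,
) -> dict[str, float]:
    """Apply the abnormality boost to fused scores.

    Requires ``query_profile.abn`` in {0, 1}.  With ABN = 0 the mapping
    is returned unchanged; with ABN = 1 every unit gains
    ``gamma * (1 + fraction)`` where the fraction is the unit's affirmed
    share of mentions (0 when it has no mentions).
    """
    if query_profile.abn not in (0, 1):
        raise ValueError("query profile must carry abn in {0, 1}")
    if query_profile.abn == 0:
        return dict(fused)
    boosted = {}
    for uid, score in fused.items():
        profile = profiles.get(uid)
        total = (profile.affirmed_count + profile.negated_count) if profile else 0
        fraction = profile.affirmed_count / total if total else 0.0
        boosted[uid] = score + config.gamma * (1.0 + fraction)
    return boosted


def rank_final(
    boosted: Mapping[str, float],
    config: FusionConfig = DEFAULT_FUSION,
) -> list[tuple[str, float]]:
    """Descending score, ties by ascending id, truncated to output depth."""
    ranked = sorted(boosted.items(), key=lambda item: (-item[1], item[0]))
    return ranked[: config.output_depth]
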