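"""Seeded synthetic collections: ontology, corpora, queries, qrels.

The generator plants the statistical structure the retrieval framework
assumes so each stage is testable offline:

* every Test concept has a representative English term, English synonym
  variants and one ASCII-safe pseudo-Korean surrogate (``kq…``) used in
  query texts, exercising the translation step;
* every concept is linked to a Disease instance whose representative
  term acts as the concept's *latent associate*: abnormal-phrased
  relevant passages and on-topic documents co-mention it (at the
  configured rate), which is the structure under which local/global
  feedback expansion can demonstrably help;
* relevant passages come in abnormal phrasing ("X has been increased",
  trigger-free, affirmed) and normal phrasing ("X is normal",
  negation-trigger-bearing, negated), mirroring the opposite relation
  between case status and negation status;
* a planting log records exactly which passages were generated for
  which concept, and qrels are derived from it.

Identical seed + config produce byte-identical serialized outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from cdsearch.corpus_index import Passage, split_sentences, write_corpus
from cdsearch.evaluation import Judgments, write_qrels
from cdsearch.ontology import Instance, Ontology, Property, save_ontology


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_concepts: int = 30
    synonyms_per_concept: int = 3
    n_passages: int = 2000
    n_documents: int = 5000
    sentences_low: int = 2
    sentences_high: int = 4
    tokens_per_sentence_low: int = 5
    tokens_per_sentence_high: int = 9
    relevance_rate: float = 0.005
    abnormal_fraction: float = 0.5
    latent_cooccurrence_rate: float = 0.85
    negation_trigger_rate: float = 1.0
    vocabulary_size: int = 400
    n_queries: int = 30
    korean_query_rate: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "relevance_rate",
            "abnormal_fraction",
            "latent_cooccurrence_rate",
            "negation_trigger_rate",
            "korean_query_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in (
            "n_concepts",
            "synonyms_per_concept",
            "n_passages",
            "n_documents",
            "vocabulary_size",
            "n_queries",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


DEFAULT_SIM = SimConfig()


@dataclass
class Query:
    query_id: str
    text: str
    qtype: str  # "normal" | "abnormal"
    concept_id: str


@dataclass
class PlantedConcept:
    """Bookkeeping for one concept's planted passages."""

    concept_id: str
    latent_term: str
    context_words: list[str] = field(default_factory=list)
    abnormal: list[str] = field(default_factory=list)
    normal: list[str] = field(default_factory=list)
    latent_abnormal: list[str] = field(default_factory=list)
    latent_normal: list[str] = field(default_factory=list)

    def all_passages(self) -> list[str]:
        return self.abnormal + self.normal + self.latent_abnormal + self.latent_normal


# -- pseudo-word machinery ----------------------------------------------

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"

# Template / trigger words the pseudo-word factory must never emit.
_RESERVED = frozenset(
    """no not normal negative has been increased high is the a was found
    abnormality stays within range test elevated level suggests patient
    requires further clinical review suspected in this case findings of
    have persisted detected screen and denote one laboratory marker
    association with reported cohorts reference ranges vary across values
    were also recorded noted patterns accompany""".split()
)


class _WordFactory:
    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._used: set[str] = set(_RESERVED)

    def word(self, prefix: str = "") -> str:
        while True:
            n_syllables = int(self._rng.integers(2, 4))
            core = "".join(
                _CONSONANTS[self._rng.integers(len(_CONSONANTS))]
                + _VOWELS[self._rng.integers(len(_VOWELS))]
                for _ in range(n_syllables)
            )
            candidate = prefix + core
            if candidate not in self._used:
                self._used.add(candidate)
                return candidate


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


# -- ontology ------------------------------------------------------------


def make_fixture_ontology(config: SimConfig = DEFAULT_SIM) -> Ontology:
    """Generate Test instances with synonym lexicons plus linked
    Disease/Specimen/Category instances."""
    rng = _stage_rng(config, 1)
    words = _WordFactory(rng)
    instances: list[Instance] = []
    properties: list[Property] = []
    specimen = Instance("S000", "Specimen", words.word())
    category = Instance("C000", "Category", words.word())
    instances.extend([specimen, category])
    for i in range(config.n_concepts):
        test_id = f"T{i:03d}"
        disease_id = f"D{i:03d}"
        representative = words.word()
        synonyms = {words.word() for _ in range(max(0, config.synonyms_per_concept - 1))}
        synonyms.add(words.word(prefix="kq"))  # pseudo-Korean surrogate
        disease = Instance(disease_id, "Disease", words.word())
        instances.append(
            Instance(
                test_id,
                "Test",
                representative,
                frozenset(synonyms),
                external_ids={"umls": f"C{1000000 + i}"},
            )
        )
        instances.append(disease)
        properties.append(Property("test_disease", test_id, disease_id))
        properties.append(Property("test_specimen", test_id, "S000"))
        properties.append(Property("test_category", test_id, "C000"))
    return Ontology(instances, properties)


# -- corpora -------------------------------------------------------------


def _english_surfaces(ontology: Ontology, test_id: str) -> list[str]:
    inst = ontology.instance(test_id)
    surfaces = [inst.representative_term.lower()]
    surfaces += sorted(s.lower() for s in inst.synonyms if not s.startswith("kq"))
    return surfaces


def _background_sentence(rng: np.random.Generator, vocab: Sequence[str], config: SimConfig) -> str:
    n = int(rng.integers(config.tokens_per_sentence_low, config.tokens_per_sentence_high + 1))
    return " ".join(vocab[int(j)] for j in rng.integers(len(vocab), size=n)) + "."


def _filler_sentence(rng: np.random.Generator, vocab: Sequence[str]) -> str:
    picks = [vocab[int(j)] for j in rng.integers(len(vocab), size=4)]
    return (
        f"Values of {picks[0]} and {picks[1]} and {picks[2]} and {picks[3]} "
        "were also recorded."
    )


def simulate_corpus(
    ontology: Ontology,
    config: SimConfig = DEFAULT_SIM,
) -> tuple[list[Passage], list[Passage], dict[str, PlantedConcept]]:
    """Generate the passage and document corpora with a planting log.

    Returns ``(passages, documents, planting)`` where ``planting`` maps
    each Test concept id to the exact ids of its generated passages by
    category.  All passages have >= 2 sentences.
    """
    rng = _stage_rng(config, 2)
    vocab = [f"bg{i:04d}" for i in range(config.vocabulary_size)]
    words = _WordFactory(rng)
    test_ids = sorted(i.id for i in ontology.instances if i.class_name == "Test")
    latent_of = {
        tid: ontology.related(tid, "test_disease")[0].representative_term.lower()
        for tid in test_ids
    }
    # concept-specific context vocabulary (symptom-like co-occurring terms)
    context_of = {tid: [words.word() for _ in range(8)] for tid in test_ids}

    n_topic = max(4, round(config.relevance_rate * config.n_passages))
    n_latent_each = 2 if n_topic >= 8 else (1 if n_topic >= 4 else 0)
    n_phrased = n_topic - 2 * n_latent_each
    n_abnormal = n_phrased // 2
    n_normal = n_phrased - n_abnormal

    def context_sentence(tid: str) -> str:
        pool = context_of[tid]
        picks = sorted(rng.choice(len(pool), size=3, replace=False).tolist())
        chosen = [pool[j] for j in picks]
        return f"{chosen[0]} {chosen[1]} {chosen[2]} findings were noted."

    drafts: list[tuple[str, str, str]] = []  # (concept_id, category, text)
    for tid in test_ids:
        latent = latent_of[tid]
        surfaces = _english_surfaces(ontology, tid)
        rep = ontology.instance(tid).representative_term.lower()
        for _ in range(n_abnormal):
            surface = surfaces[int(rng.integers(len(surfaces)))]
            first = (
                f"{surface} has been increased."
                if rng.random() < 0.5
                else f"{surface} is high."
            )
            if rng.random() < config.latent_cooccurrence_rate:
                second = f"Elevated {rep} level suggests {latent} in the patient."
            else:
                second = f"Elevated {rep} level requires further clinical review."
            text = f"{first} {second} {context_sentence(tid)} {_filler_sentence(rng, vocab)}"
            drafts.append((tid, "abnormal", text))
        for _ in range(n_normal):
            surface = surfaces[int(rng.integers(len(surfaces)))]
            if rng.random() < config.negation_trigger_rate:
                first = (
                    f"{surface} is normal."
                    if rng.random() < 0.5
                    else f"No {surface} abnormality was found."
                )
            else:
                first = f"{surface} stays within range."
            second = f"The {rep} test is negative."
            text = f"{first} {second} {_filler_sentence(rng, vocab)}"
            drafts.append((tid, "normal", text))
        for _ in range(n_latent_each):
            # retrievable essentially only via the latent associate term
            # (tf 2), never via a surface of the concept itself
            one_ctx = context_of[tid][int(rng.integers(len(context_of[tid])))]
            drafts.append(
                (
                    tid,
                    "latent_abnormal",
                    f"{latent} is suspected in this case. "
                    f"Recurrent {latent} {one_ctx} findings were noted.",
                )
            )
            drafts.append(
                (
                    tid,
                    "latent_normal",
                    f"No {latent} was detected. The {latent} screen is negative.",
                )
            )

    n_background = max(0, config.n_passages - len(drafts))
    for _ in range(n_background):
        n_sentences = int(rng.integers(config.sentences_low, config.sentences_high + 1))
        text = " ".join(_background_sentence(rng, vocab, config) for _ in range(n_sentences))
        drafts.append(("", "background", text))

    order = rng.permutation(len(drafts))
    planting = {
        tid: PlantedConcept(
            concept_id=tid, latent_term=latent_of[tid], context_words=list(context_of[tid])
        )
        for tid in test_ids
    }
    passages: list[Passage] = []
    sources = ("book1", "book2", "book3")
    for new_pos, old in enumerate(order):
        tid, category, text = drafts[int(old)]
        pid = f"p{new_pos:05d}"
        passages.append(
            Passage(
                passage_id=pid,
                source_id=sources[new_pos % len(sources)],
                position=new_pos,
                text=text,
                sentence_count=len(split_sentences(text)),
            )
        )
        if category != "background":
            getattr(planting[tid], category).append(pid)

    # global document corpus
    n_topic_docs = max(3, round(0.004 * config.n_documents))
    doc_drafts: list[str] = []
    for tid in test_ids:
        latent = latent_of[tid]
        surfaces = _english_surfaces(ontology, tid)
        rep = ontology.instance(tid).representative_term.lower()
        context = context_of[tid]
        for _ in range(n_topic_docs):
            synonym = surfaces[int(rng.integers(len(surfaces)))]
            first = f"{rep} and {synonym} denote one laboratory marker."
            if rng.random() < config.latent_cooccurrence_rate:
                second = f"Association of {rep} with {latent} is reported across cohorts."
            else:
                second = f"Reference ranges of {rep} vary across cohorts."
            picks = sorted(rng.choice(len(context), size=3, replace=False).tolist())
            third = (
                f"{context[picks[0]]} {context[picks[1]]} {context[picks[2]]} "
                f"patterns accompany {latent} in cohorts."
            )
            doc_drafts.append(f"{first} {second} {third}")
    for _ in range(max(0, config.n_documents - len(doc_drafts))):
        n_sentences = int(rng.integers(config.sentences_low, config.sentences_high + 1))
        doc_drafts.append(
            " ".join(_background_sentence(rng, vocab, config) for _ in range(n_sentences))
        )
    doc_order = rng.permutation(len(doc_drafts))
    documents = [
        Passage(
            passage_id=f"g{new_pos:05d}",
            source_id="pmc",
            position=new_pos,
            text=doc_drafts[int(old)],
            sentence_count=len(split_sentences(doc_drafts[int(old)])),
        )
        for new_pos, old in enumerate(doc_order)
    ]
    return passages, documents, planting


# -- queries and qrels ---------------------------------------------------


def simulate_queries_qrels(
    ontology: Ontology,
    planting: dict[str, PlantedConcept],
    config: SimConfig = DEFAULT_SIM,
) -> tuple[list[Query], Judgments]:
    """Generate case-report queries and graded judgments.

    Abnormal queries ("X has been increased") mark abnormal-description
    passages definitely relevant and normal-description passages not
    relevant; normal queries ("X is normal") mark normal-description
    passages definitely relevant and abnormal-description ones possibly
    relevant.
    """
    rng = _stage_rng(config, 3)
    test_ids = sorted(planting)
    n_abnormal = round(config.n_queries * config.abnormal_fraction)
    queries: list[Query] = []
    judgments = Judgments()
    for i in range(config.n_queries):
        tid = test_ids[i % len(test_ids)]
        qtype = "abnormal" if i < n_abnormal else "normal"
        inst = ontology.instance(tid)
        korean = sorted(s for s in inst.synonyms if s.startswith("kq"))
        english = _english_surfaces(ontology, tid)
        if korean and rng.random() < config.korean_query_rate:
            surface = korean[int(rng.integers(len(korean)))]
        else:
            surface = english[int(rng.integers(len(english)))]
        if qtype == "abnormal":
            text = (
                f"{surface} has been increased."
                if rng.random() < 0.5
                else f"{surface} is high."
            )
        else:
            text = f"{surface} is normal." if rng.random() < 0.5 else f"No {surface}."
        qid = f"q{i:03d}"
        queries.append(Query(qid, text, qtype, tid))
        plant = planting[tid]
        if qtype == "abnormal":
            for pid in plant.abnormal + plant.latent_abnormal:
                judgments.add(qid, pid, 2)
            for pid in plant.normal + plant.latent_normal:
                judgments.add(qid, pid, 0)
        else:
            for pid in plant.normal + plant.latent_normal:
                judgments.add(qid, pid, 2)
            for pid in plant.abnormal + plant.latent_abnormal:
                judgments.add(qid, pid, 1)
    return queries, judgments


# -- full fixture on disk ------------------------------------------------


def write_queries(queries: Sequence[Query], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in queries:
            fh.write(f"{q.query_id}\t{q.qtype}\t{q.concept_id}\t{q.text}\n")


def read_queries(path: str | Path) -> list[Query]:
    queries = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            qid, qtype, concept_id, text = line.split("\t", 3)
            queries.append(Query(qid, text, qtype, concept_id))
    return queries


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and serialize a complete fixture collection.

    Writes ``ontology.json``, ``passages.jsonl``, ``documents.jsonl``,
    ``queries.tsv``, ``qrels.txt`` and ``planting.json``; returns the
    path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ontology = make_fixture_ontology(config)
    passages, documents, planting = simulate_corpus(ontology, config)
    queries, judgments = simulate_queries_qrels(ontology, planting, config)
    paths = {
        "ontology": out / "ontology.json",
        "passages": out / "passages.jsonl",
        "documents": out / "documents.jsonl",
        "queries": out / "queries.tsv",
        "qrels": out / "qrels.txt",
        "planting": out / "planting.json",
    }
    save_ontology(ontology, paths["ontology"])
    write_corpus(passages, paths["passages"])
    write_corpus(documents, paths["documents"])
    write_queries(queries, paths["queries"])
    write_qrels(judgments, paths["qrels"])
    paths["planting"].write_text(
        json.dumps({tid: asdict(p) for tid, p in sorted(planting.items())}, indent=2)
        + "\n",
        encoding="utf-8",
    )
    return paths
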