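"""Shared fixtures: hand-built ontologies and small synthetic collections."""

from __future__ import annotations

import pytest

from cdsearch.ontology import Instance, Ontology, Property
from cdsearch.synthetic_fixtures import (
    SimConfig,
    make_fixture_ontology,
    simulate_corpus,
    simulate_queries_qrels,
)


@pytest.fixture(scope="session")
def lab_ontology() -> Ontology:
    """Small hand-built ontology with multilingual synonyms."""
    return Ontology(
        instances=[
            Instance(
                "T001",
                "Test",
                "Platelet",
                frozenset({"PFA", "blood disk", "PFT", "thrombocyte", "혈소판"}),
                external_ids={"umls": "C0005821"},
            ),
            Instance(
                "T002",
                "Test",
                "AFP",
                frozenset({"alpha-fetoprotein", "total afp"}),
            ),
            Instance("D001", "Disease", "anemia", frozenset({"anaemia"})),
            Instance("C001", "Category", "Inflammation", frozenset({"inflammatory"})),
            Instance("S001", "Specimen", "serum"),
        ],
        properties=[
            Property("test_disease", "T001", "D001"),
            Property("test_category", "T001", "C001"),
            Property("test_specimen", "T001", "S001"),
        ],
    )


@pytest.fixture(scope="session")
def clinical_ontology() -> Ontology:
    """Concepts for the six worked example sentences."""
    return Ontology(
        instances=[
            Instance("T010", "Test", "AFP", frozenset({"alpha-fetoprotein"})),
            Instance("D010", "Disease", "anemia"),
            Instance("T011", "Test", "HIV test", frozenset({"hiv"})),
            Instance("T012", "Test", "Eosinophil"),
            Instance("T013", "Test", "uric acid concentration", frozenset({"uric acid"})),
            Instance("T014", "Test", "Bilirubin"),
        ]
    )


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Scaled-down collection for fast pipeline tests."""
    return SimConfig(
        seed=7,
        n_concepts=8,
        n_passages=300,
        n_documents=500,
        n_queries=8,
        vocabulary_size=120,
    )


@pytest.fixture(scope="session")
def small_collection(small_sim_config):
    ontology = make_fixture_ontology(small_sim_config)
    passages, documents, planting = simulate_corpus(ontology, small_sim_config)
    queries, judgments = simulate_queries_qrels(ontology, planting, small_sim_config)
    return {
        "config": small_sim_config,
        "ontology": ontology,
        "passages": passages,
        "documents": documents,
        "planting": planting,
        "queries": queries,
        "judgments": judgments,
    }
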