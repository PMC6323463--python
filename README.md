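# cdsearch

Clinical decision-support passage retrieval over biomedical text.  The
engine detects medical concepts in short case-report queries through a
domain ontology (translating local-language surfaces to representative
English terms), expands them with weighted synonyms, reformulates the
query with multilevel pseudo-relevance feedback (local passage corpus +
global document corpus, convexly fused), scores passages under three
retrieval models (TF-IDF, BM25, Dirichlet language model) with
normalized score fusion, and re-ranks with a negation-differential
boost that favors affirmed-concept passages for abnormal-case queries.

Everything is testable offline: a seeded synthetic-collection generator
produces ontologies, passage/document corpora, case-report queries and
graded TREC-style judgments with the statistical structure the pipeline
assumes (synonym variants, normal vs. abnormal phrasing with negation
triggers, latent concept-disease co-occurrence).

## Layout

| module | contents |
| --- | --- |
| `cdsearch.ontology` | ontology schema, validation, concept detection/translation, synonym expansion |
| `cdsearch.corpus_index` | passage splitting (paragraphs with ≥ 2 sentences), tokenization, inverted indexes, JSONL corpus I/O |
| `cdsearch.retrieval_models` | TF-IDF / BM25 / Dirichlet-LM scoring of weighted queries, top-k retrieval |
| `cdsearch.prf_expansion` | feedback term weighting, local/global fusion, top-m query reformulation |
| `cdsearch.negation` | trigger-window polarity detection, "no-" prefix transform, query abnormality, passage polarity profiles |
| `cdsearch.ranking` | per-model min-max normalization, pooled score fusion, abnormality boost, final ranking |
| `cdsearch.evaluation` | TREC qrels/run I/O, P@N, R-precision, nDCG, MRR, paired t-tests |
| `cdsearch.synthetic_fixtures` | seeded generator for ontology, corpora, queries and qrels |
| `cdsearch.pipeline` | end-to-end orchestration and the five named configurations (baseline, UMLSE, LPRF, GPRF, GPRF-NEG) |
| `cdsearch.cli` | command-line interface |

Key defaults: synonym weight 0.5; feedback smoothing α = 2, β = 0.75,
depth k = 5; local/global mix λ = 0.65; expansion size m = 35;
LM prior μ = 2500; BM25 k1 = 1.2, b = 0.75; fusion pool M = 100;
boost γ = 2.0; run depth 500.

## CLI

```sh
# generate a seeded synthetic collection
cdsearch simulate --seed 1 --out fixture/

# run all queries under one configuration and write a TREC run file
cdsearch batch-run --queries fixture/queries.tsv --ontology fixture/ontology.json \
    --passages fixture/passages.jsonl --documents fixture/documents.jsonl \
    --config gprf-neg --out run.txt

# evaluate and compare runs
cdsearch eval --run run.txt --qrels fixture/qrels.txt
cdsearch compare --run-a run.txt --run-b other.txt --qrels fixture/qrels.txt --metric p5

# single query, concept inspection, expansion table
cdsearch search --query "AFP is normal." --ontology fixture/ontology.json \
    --passages fixture/passages.jsonl --documents fixture/documents.jsonl
cdsearch negate --text "AFP is normal." --ontology fixture/ontology.json
cdsearch expand --query "AFP is high." --ontology fixture/ontology.json \
    --passages fixture/passages.jsonl --documents fixture/documents.jsonl
cdsearch ontology validate fixture/ontology.json
cdsearch index build --corpus fixture/passages.jsonl --out idx/
```

## Ontology file format

A JSON object with an `instances` array (and optional `properties`):

```json
{
  "instances": [
    {
      "id": "T001",
      "class": "Test",
      "representative_term": "Platelet",
      "synonyms": ["PFA", "blood disk", "혈소판"],
      "external_ids": {"umls": "C0005821"}
    }
  ],
  "properties": [
    {"type": "test_disease", "source": "T001", "target": "D001"}
  ]
}
```

Classes are restricted to `Test`, `Specimen`, `Category`, `Disease`;
every surface form (representative term or synonym, case-folded) must
map to exactly one instance.  Corpora are line-delimited JSON records
with `passage_id`, `source_id`, `position`, `text`, and optional
`links`.
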