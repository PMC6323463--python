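import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdsearch.negation import (
    DEFAULT_NEGATION,
    NegationLexicon,
    analyze_text,
    apply_no_prefix,
    detect_polarity,
    passage_polarity_counts,
    query_abnormality,
)
from cdsearch.corpus_index import Passage
from cdsearch.ontology import ConceptMention, detect_and_translate
from cdsearch.query import QueryTerm, WeightedQuery

# the six worked sentences and their printed status
WORKED_SENTENCES = [
    ("AFP is normal", "negated"),
    ("No anemia", "negated"),
    ("HIV test is negative", "negated"),
    ("Eosinophil has been increased", "affirmed"),
    ("The uric acid concentration has increased", "affirmed"),
    ("Bilirubin is high", "affirmed"),
]


class TestLexicon:
    def test_default_contents(self):
        triggers = DEFAULT_NEGATION.pre_triggers | DEFAULT_NEGATION.post_triggers
        assert {"no", "not", "negative", "normal"} <= triggers

    def test_empty_triggers_rejected(self):
        with pytest.raises(ValueError):
            NegationLexicon(pre_triggers=frozenset(), post_triggers=frozenset({"x"}))

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            NegationLexicon(window=0)


class TestDetectPolarity:
    @pytest.mark.parametrize("sentence,expected", WORKED_SENTENCES)
    def test_worked_sentences(self, clinical_ontology, sentence, expected):
        _, _, mentions = analyze_text(sentence, clinical_ontology)
        assert len(mentions) == 1, sentence
        assert mentions[0].polarity == expected

    def test_span_out_of_range(self):
        mention = ConceptMention("T1", "x", "x", (5, 6))
        with pytest.raises(ValueError, match="out of range"):
            detect_polarity(["a", "b"], [mention])

    def test_scope_is_sentence_bounded(self, clinical_ontology):
        # "no" in the first sentence must not negate a concept in the second
        text = "There is no record here. Bilirubin is high."
        _, _, mentions = analyze_text(text, clinical_ontology)
        assert [m.polarity for m in mentions] == ["affirmed"]

    def test_window_limit(self):
        tokens = "not w1 w2 w3 w4 w5 concept".split()
        mention = ConceptMention("T1", "concept", "concept", (6, 7))
        out = detect_polarity(tokens, [mention], NegationLexicon(window=5))
        assert out[0].polarity == "affirmed"  # trigger 6 tokens away
        out = detect_polarity(tokens, [mention], NegationLexicon(window=6))
        assert out[0].polarity == "negated"

    @given(st.sampled_from(WORKED_SENTENCES), st.sampled_from(WORKED_SENTENCES))
    @settings(max_examples=36, deadline=None)
    def test_concatenation_keeps_per_sentence_status(
        self, clinical_ontology, first, second
    ):
        text = f"{first[0]}. {second[0]}."
        _, _, mentions = analyze_text(text, clinical_ontology)
        assert [m.polarity for m in mentions] == [first[1], second[1]]


class TestApplyNoPrefix:
    def _mentions(self, clinical_ontology, text):
        _, _, mentions = analyze_text(text, clinical_ontology)
        return mentions

    def test_negated_synonym_prefixed(self, clinical_ontology):
        mentions = self._mentions(clinical_ontology, "AFP is normal")
        query = WeightedQuery(
            [
                QueryTerm("afp", 1.0, "original", "T010"),
                QueryTerm("alpha-fetoprotein", 0.5, "synonym", "T010"),
            ]
        )
        out = apply_no_prefix(query, mentions)
        assert [t.term for t in out.terms] == ["afp", "no-alpha-fetoprotein"]
        assert out.terms[1].neg_prefixed
        assert out.terms[1].weight == 0.5
        assert not out.terms[0].neg_prefixed  # original never modified

    def test_affirmed_unchanged(self, clinical_ontology):
        mentions = self._mentions(clinical_ontology, "Bilirubin is high")
        query = WeightedQuery(
            [
                QueryTerm("bilirubin", 1.0, "original", "T014"),
                QueryTerm("bili", 0.5, "synonym", "T014"),
            ]
        )
        out = apply_no_prefix(query, mentions)
        assert [t.term for t in out.terms] == ["bilirubin", "bili"]

    def test_no_synonym_terms_unchanged(self, clinical_ontology):
        mentions = self._mentions(clinical_ontology, "AFP is normal")
        query = WeightedQuery([QueryTerm("afp", 1.0, "original", "T010")])
        assert apply_no_prefix(query, mentions).terms == query.terms

    def test_prf_terms_never_prefixed(self, clinical_ontology):
        mentions = self._mentions(clinical_ontology, "AFP is normal")
        query = WeightedQuery([QueryTerm("latent", 0.9, "prf")])
        assert apply_no_prefix(query, mentions).terms == query.terms

    def test_idempotent(self, clinical_ontology):
        mentions = self._mentions(clinical_ontology, "AFP is normal")
        query = WeightedQuery(
            [QueryTerm("alpha-fetoprotein", 0.5, "synonym", "T010")]
        )
        once = apply_no_prefix(query, mentions)
        twice = apply_no_prefix(once, mentions)
        assert once.terms == twice.terms
        assert once.terms[0].term == "no-alpha-fetoprotein"


class TestQueryAbnormality:
    def _mention(self, polarity):
        return ConceptMention("T1", "x", "x", (0, 1), polarity)

    def test_one_negated(self):
        profile = query_abnormality([self._mention("negated")])
        assert (profile.affirmed_count, profile.negated_count, profile.abn) == (0, 1, 0)

    def test_one_affirmed(self):
        assert query_abnormality([self._mention("affirmed")]).abn == 1

    def test_tie_is_abnormal(self):
        mentions = [self._mention("affirmed")] * 2 + [self._mention("negated")] * 2
        assert query_abnormality(mentions).abn == 1

    def test_concept_free_query_is_abnormal(self):
        assert query_abnormality([]).abn == 1

    def test_unassessed_rejected(self):
        with pytest.raises(ValueError, match="unassessed"):
            query_abnormality([ConceptMention("T1", "x", "x", (0, 1))])


class TestPassageCounts:
    def _passage(self, text):
        return Passage("p1", "s", 0, text, 2)

    def test_two_affirmed(self, clinical_ontology):
        profile = passage_polarity_counts(
            self._passage("Eosinophil has been increased. Bilirubin is high."),
            clinical_ontology,
        )
        assert (profile.affirmed_count, profile.negated_count) == (2, 0)
        assert profile.abn is None

    def test_no_concepts(self, clinical_ontology):
        profile = passage_polarity_counts(
            self._passage("Nothing of note. Plain text here."), clinical_ontology
        )
        assert (profile.affirmed_count, profile.negated_count) == (0, 0)

    def test_negative_test_result(self, clinical_ontology):
        profile = passage_polarity_counts(
            self._passage("HIV test is negative. Repeat later."), clinical_ontology
        )
        assert (profile.affirmed_count, profile.negated_count) == (0, 1)

    def test_repeated_concept_counts_per_mention(self, clinical_ontology):
        profile = passage_polarity_counts(
            self._passage("Bilirubin is high. Bilirubin has been increased."),
            clinical_ontology,
        )
        assert profile.affirmed_count == 2
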