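"""Domain ontology: loading, validation, concept detection and translation.

The ontology is a flat JSON document (documented in the README) holding
instances of four closed classes — Test, Specimen, Category, Disease —
each with a single representative English term, a multilingual synonym
set, optional external identifiers, and typed relations between
instances.  The lexicon derived from it (surface term -> instance id)
drives concept detection: local-language surfaces translate to the
instance's representative English term, and unknown surfaces are simply
discarded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

from cdsearch.query import QueryTerm

logger = logging.getLogger(__name__)

VALID_CLASSES = frozenset({"Test", "Specimen", "Category", "Disease"})
VALID_PROPERTY_TYPES = frozenset({"test_specimen", "test_category", "test_disease"})

#: Polarity labels carried by concept mentions.
POLARITIES = ("unassessed", "affirmed", "negated")


class OntologyError(ValueError):
    """Base class for ontology problems."""


class OntologyFormatError(OntologyError):
    """The file could not be parsed as the documented JSON schema."""


class OntologyValidationError(OntologyError):
    """The file parsed but violates an ontology invariant."""


def fold_term(term: str) -> str:
    """Case-fold a surface term: ASCII upper -> lower, non-Latin verbatim."""
    return term.lower()


@dataclass(frozen=True)
class Property:
    """A typed relation between two instances (e.g. test -> disease)."""

    type: str
    source: str
    target: str


@dataclass(frozen=True)
class Instance:
    id: str
    class_name: str
    representative_term: str
    synonyms: frozenset[str] = frozenset()
    external_ids: Mapping[str, str] = field(default_factory=dict)

    def surfaces(self) -> set[str]:
        """All case-folded surface forms naming this instance."""
        return {fold_term(self.representative_term)} | {fold_term(s) for s in self.synonyms}


@dataclass
class ConceptMention:
    """A lexicon match in a token sequence.

    ``span`` is a half-open ``(start, end)`` token-offset pair.  Polarity
    stays ``unassessed`` until negation detection runs.
    """

    instance_id: str
    surface: str
    representative_term: str
    span: tuple[int, int]
    polarity: str = "unassessed"

    def __post_init__(self) -> None:
        start, end = self.span
        if not start < end:
            raise ValueError(f"mention span must satisfy start < end, got {self.span}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")


class Ontology:
    """Validated ontology with a derived surface-form lexicon."""

    def __init__(
        self,
        instances: Sequence[Instance],
        properties: Sequence[Property] = (),
    ) -> None:
        self.instances: list[Instance] = list(instances)
        self.properties: list[Property] = list(properties)
        self.classes: set[str] = {inst.class_name for inst in self.instances}
        self._by_id: dict[str, Instance] = {}
        self.lexicon: dict[str, str] = {}
        self._validate()

    # -- validation -------------------------------------------------

    def _validate(self) -> None:
        for inst in self.instances:
            if inst.class_name not in VALID_CLASSES:
                raise OntologyValidationError(
                    f"instance {inst.id!r}: class {inst.class_name!r} not in "
                    f"{sorted(VALID_CLASSES)}"
                )
            if inst.id in self._by_id:
                raise OntologyValidationError(f"duplicate instance id {inst.id!r}")
            if not inst.representative_term:
                raise OntologyValidationError(
                    f"instance {inst.id!r}: empty representative term"
                )
            rep = fold_term(inst.representative_term)
            folded_syns = [fold_term(s) for s in inst.synonyms]
            if rep in folded_syns:
                raise OntologyValidationError(
                    f"instance {inst.id!r}: representative term duplicated in synonyms"
                )
            if len(folded_syns) != len(set(folded_syns)):
                raise OntologyValidationError(
                    f"instance {inst.id!r}: synonyms collide after case-folding"
                )
            for source, ident in inst.external_ids.items():
                if not ident:
                    raise OntologyValidationError(
                        f"instance {inst.id!r}: empty external id for {source!r}"
                    )
            self._by_id[inst.id] = inst
            for surface in inst.surfaces():
                owner = self.lexicon.get(surface)
                if owner is not None and owner != inst.id:
                    raise OntologyValidationError(
                        f"surface {surface!r} maps to both {owner!r} and {inst.id!r}"
                    )
                self.lexicon[surface] = inst.id
        for prop in self.properties:
            if prop.type not in VALID_PROPERTY_TYPES:
                raise OntologyValidationError(f"unknown property type {prop.type!r}")
            for end in (prop.source, prop.target):
                if end not in self._by_id:
                    raise OntologyValidationError(
                        f"property {prop.type!r} references unknown instance {end!r}"
                    )

    # -- queries ----------------------------------------------------

    def instance(self, instance_id: str) -> Instance:
        return self._by_id[instance_id]

    def __contains__(self, instance_id: str) -> bool:
        return instance_id in self._by_id

    def lookup(self, surface: str) -> Optional[Instance]:
        """Resolve a (possibly multi-word) surface term to its instance."""
        iid = self.lexicon.get(fold_term(surface))
        return self._by_id[iid] if iid is not None else None

    def synonyms_of(self, instance_id: str) -> set[str]:
        """Case-folded synonym surfaces of an instance (representative excluded)."""
        inst = self._by_id[instance_id]
        return {fold_term(s) for s in inst.synonyms}

    def related(self, instance_id: str, property_type: str) -> list[Instance]:
        return [
            self._by_id[p.target]
            for p in self.properties
            if p.type == property_type and p.source == instance_id
        ]

    def max_surface_tokens(self) -> int:
        """Longest surface form in the lexicon, in whitespace tokens."""
        return max((len(s.split()) for s in self.lexicon), default=1)

    # -- serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": sorted(VALID_CLASSES),
            "instances": [
                {
                    "id": inst.id,
                    "class": inst.class_name,
                    "representative_term": inst.representative_term,
                    "synonyms": sorted(inst.synonyms),
                    "external_ids": dict(sorted(inst.external_ids.items())),
                }
                for inst in sorted(self.instances, key=lambda i: i.id)
            ],
            "properties": [
                {"type": p.type, "source": p.source, "target": p.target}
                for p in sorted(self.properties, key=lambda p: (p.type, p.source, p.target))
            ],
        }


def load_ontology(path: str | Path) -> Ontology:
    """Load and validate an ontology JSON file.

    Raises :class:`OntologyFormatError` on parse problems (naming the
    offending record) and :class:`OntologyValidationError` on invariant
    violations (naming the instance).
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise OntologyFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(raw, dict) or "instances" not in raw:
        raise OntologyFormatError(f"{path}: expected an object with an 'instances' array")
    instances = []
    for i, rec in enumerate(raw["instances"]):
        try:
            instances.append(
                Instance(
                    id=str(rec["id"]),
                    class_name=str(rec["class"]),
                    representative_term=str(rec["representative_term"]),
                    synonyms=frozenset(map(str, rec.get("synonyms", []))),
                    external_ids=dict(rec.get("external_ids", {})),
                )
            )
        except (KeyError, TypeError) as exc:
            raise OntologyFormatError(f"{path}: bad instance record #{i}: {exc}") from exc
    properties = []
    for i, rec in enumerate(raw.get("properties", [])):
        try:
            properties.append(
                Property(type=str(rec["type"]), source=str(rec["source"]), target=str(rec["target"]))
            )
        except (KeyError, TypeError) as exc:
            raise OntologyFormatError(f"{path}: bad property record #{i}: {exc}") from exc
    return Ontology(instances, properties)


def save_ontology(ontology: Ontology, path: str | Path) -> None:
    """Write the canonical JSON form (sorted keys, sorted records)."""
    Path(path).write_text(
        json.dumps(ontology.to_dict(), ensure_ascii=False, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def detect_and_translate(
    tokens: Sequence[str],
    ontology: Ontology,
    max_ngram: int = 4,
) -> list[ConceptMention]:
    """Scan a token sequence for lexicon matches, longest-match-first.

    Contiguous token n-grams (joined by single spaces, up to
    ``max_ngram`` tokens) are looked up in the lexicon; at each position
    the longest match wins and scanning resumes after it, which makes
    the resolution longest-match-first with leftmost tie-breaking.
    Every mention's ``representative_term`` is the instance's English
    representative; tokens matching nothing yield no mention.
    """
    mentions: list[ConceptMention] = []
    n = len(tokens)
    folded = [fold_term(t) for t in tokens]
    i = 0
    while i < n:
        matched = False
        for width in range(min(max_ngram, n - i), 0, -1):
            surface = " ".join(folded[i : i + width])
            iid = ontology.lexicon.get(surface)
            if iid is not None:
                inst = ontology.instance(iid)
                mentions.append(
                    ConceptMention(
                        instance_id=iid,
                        surface=surface,
                        representative_term=fold_term(inst.representative_term),
                        span=(i, i + width),
                    )
                )
                i += width
                matched = True
                break
        if not matched:
            i += 1
    return mentions


#: A synonym provider maps a representative term to a set of synonym surfaces.
SynonymProvider = Callable[[str], set[str]]


class OntologySynonymProvider:
    """Default provider backed by the ontology's own lexicon."""

    def __init__(self, ontology: Ontology) -> None:
        self._ontology = ontology

    def __call__(self, representative_term: str) -> set[str]:
        inst = self._ontology.lookup(representative_term)
        if inst is None:
            return set()
        return self._ontology.synonyms_of(inst.id)


def expand_synonyms(
    mentions: Iterable[ConceptMention],
    provider: SynonymProvider,
    weight: float = 0.5,
) -> list[QueryTerm]:
    """Turn concept mentions into weighted query terms with synonyms.

    Representative terms enter with weight 1.0 and origin ``original``;
    each synonym enters once with the configured ``weight`` and origin
    ``synonym``.  Duplicates of already-present terms are not re-added.
    A provider failure downgrades to the original terms with a warning.
    """
    terms: list[QueryTerm] = []
    seen: set[str] = set()
    for mention in mentions:
        rep = fold_term(mention.representative_term)
        if rep not in seen:
            seen.add(rep)
            terms.append(QueryTerm(rep, 1.0, "original", mention.instance_id))
    for mention in mentions:
        rep = fold_term(mention.representative_term)
        try:
            synonyms = provider(rep)
        except Exception:  # noqa: BLE001 - external providers may fail arbitrarily
            logger.warning("synonym provider failed for %r; expansion skipped", rep)
            continue
        for syn in sorted(fold_term(s) for s in synonyms):
            if syn in seen:
                continue
            seen.add(syn)
            terms.append(QueryTerm(syn, weight, "synonym", mention.instance_id))
    return terms
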