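"""Semantic-triple knowledge graph: concepts, typed relations, triples, adjacency.

The atomic unit of clinical knowledge here is the semantic triple
subject--relation--object over coded concepts (e.g. a medication code
``treats`` a disorder code). A :class:`KnowledgeGraph` is a set of such
triples together with a relation registry that records, per relation type,
whether its triples are eligible for retrieval-augmented context generation
(the ``rag_use`` flag; 13 of the 40 default relations are eligible).

File format: UTF-8 TSV with columns
``subject, relation, object[, subject_label, subject_tag, object_label, object_tag, provenance]``
(first three required; ``#``-prefixed header lines ignored; no quoting).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "Concept",
    "RelationType",
    "SemanticTriple",
    "RelationRegistry",
    "KnowledgeGraph",
    "TripleParseError",
    "default_registry",
    "load_triples",
    "save_triples",
    "normalize_relation",
]


class TripleParseError(ValueError):
    """Raised when a triple TSV row cannot be parsed."""


_WS = re.compile(r"\s+")


def normalize_relation(name: str) -> str:
    """Lower-case a relation name and collapse internal whitespace."""
    return _WS.sub(" ", name.strip()).lower()


@dataclass(frozen=True)
class Concept:
    """A coded clinical concept.

    ``code`` is an opaque identifier (stand-in for terminology codes);
    ``label`` the preferred human-readable term; ``semantic_tag`` a category
    string such as "disorder", "finding" or "procedure" (may be empty).
    """

    code: str
    label: str = ""
    semantic_tag: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("concept code must be nonempty")

    @property
    def display_label(self) -> str:
        return self.label if self.label else self.code


@dataclass(frozen=True)
class RelationType:
    """A typed relation; ``rag_use`` marks context-generation eligibility."""

    name: str
    rag_use: bool = False
    count_hint: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("relation name must be nonempty")
        if self.count_hint is not None and self.count_hint < 0:
            raise ValueError("count_hint must be nonnegative")


@dataclass(frozen=True, order=True)
class SemanticTriple:
    """One subject--relation--object statement over concept codes."""

    subject: str
    relation: str
    object: str
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.subject or not self.object:
            raise ValueError("triple subject and object must be nonempty")
        if not self.relation:
            raise ValueError("triple relation must be nonempty")

    def key(self) -> tuple[str, str, str]:
        return (self.subject, self.relation, self.object)


class RelationRegistry:
    """Mutable set of :class:`RelationType`, keyed by normalized name."""

    def __init__(self, relations: Iterable[RelationType] = ()) -> None:
        self._by_name: dict[str, RelationType] = {}
        for rel in relations:
            self.add(rel)

    def add(self, rel: RelationType) -> None:
        name = normalize_relation(rel.name)
        if name != rel.name:
            rel = RelationType(name, rel.rag_use, rel.count_hint)
        if name in self._by_name and self._by_name[name] != rel:
            raise ValueError(f"conflicting registration for relation {name!r}")
        self._by_name[name] = rel

    def __contains__(self, name: str) -> bool:
        return normalize_relation(name) in self._by_name

    def __getitem__(self, name: str) -> RelationType:
        return self._by_name[normalize_relation(name)]

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self) -> Iterator[RelationType]:
        return iter(sorted(self._by_name.values(), key=lambda r: r.name))

    def names(self) -> frozenset[str]:
        return frozenset(self._by_name)

    def rag_relations(self) -> frozenset[str]:
        """Names of relations whose triples may enter a RAG context."""
        return frozenset(n for n, r in self._by_name.items() if r.rag_use)

    def copy(self) -> "RelationRegistry":
        return RelationRegistry(self._by_name.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RelationRegistry):
            return NotImplemented
        return self._by_name == other._by_name


def default_registry() -> RelationRegistry:
    """The shipped 40-relation registry (13 flagged ``rag_use``).

    ``count_hint`` values are corpus-scale triple frequencies used as the
    default relation mix when sampling synthetic graphs.
    """
    raw = json.loads(
        resources.files("scai.data").joinpath("relation_registry.json").read_text("utf-8")
    )
    return RelationRegistry(
        RelationType(r["name"], r["rag_use"], r.get("count_hint")) for r in raw["relations"]
    )


class KnowledgeGraph:
    """Triple store with concept table, relation registry and adjacency index.

    Duplicate (subject, relation, object) triples collapse silently; unknown
    relations are auto-registered with ``rag_use=False`` and a warning, so
    storage is fail-open while context generation stays fail-closed.
    """

    def __init__(self, registry: Optional[RelationRegistry] = None) -> None:
        self.registry = registry if registry is not None else default_registry()
        self.concepts: dict[str, Concept] = {}
        self._triples: dict[tuple[str, str, str], SemanticTriple] = {}
        self._adjacency: dict[str, set[tuple[str, str, str]]] = {}

    # -- construction -------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        existing = self.concepts.get(concept.code)
        if existing is None:
            self.concepts[concept.code] = concept
        elif (concept.label or concept.semantic_tag) and not (
            existing.label or existing.semantic_tag
        ):
            # richer annotation wins over a bare placeholder
            self.concepts[concept.code] = concept

    def ensure_concept(self, code: str, label: str = "", tag: str = "") -> Concept:
        self.add_concept(Concept(code, label, tag))
        return self.concepts[code]

    def add_triple(self, triple: SemanticTriple) -> bool:
        """Add a triple; returns False when it was already present."""
        relation = normalize_relation(triple.relation)
        if relation != triple.relation:
            triple = SemanticTriple(triple.subject, relation, triple.object, triple.provenance)
        if relation not in self.registry:
            logger.warning(
                "unknown relation %r registered with rag_use=False", relation
            )
            self.registry.add(RelationType(relation, rag_use=False))
        key = triple.key()
        if key in self._triples:
            logger.debug("duplicate triple collapsed: %s", key)
            return False
        self.ensure_concept(triple.subject)
        self.ensure_concept(triple.object)
        self._triples[key] = triple
        for code in (triple.subject, triple.object):
            self._adjacency.setdefault(code, set()).add(key)
        return True

    # -- queries ------------------------------------------------------

    @property
    def triples(self) -> list[SemanticTriple]:
        return sorted(self._triples.values())

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, triple: SemanticTriple) -> bool:
        return triple.key() in self._triples

    def concept(self, code: str) -> Concept:
        """Concept record for ``code``; a bare fallback if unregistered."""
        return self.concepts.get(code, Concept(code))

    def neighbors(
        self, code: str, allowed: Optional[Iterable[str]] = None
    ) -> list[SemanticTriple]:
        """Every triple in which ``code`` is subject or object.

        Restricted to ``allowed`` relation names when given. Ordered by
        (relation, counterpart code, subject) so downstream context files are
        reproducible byte-for-byte. Unknown codes yield an empty list.
        """
        keys = self._adjacency.get(code, ())
        allowed_set = (
            None if allowed is None else {normalize_relation(a) for a in allowed}
        )
        out = []
        for key in keys:
            t = self._triples[key]
            if allowed_set is not None and t.relation not in allowed_set:
                continue
            out.append(t)
        out.sort(
            key=lambda t: (
                t.relation,
                t.object if t.subject == code else t.subject,
                t.subject,
                t.object,
            )
        )
        return out

    def deconstruct(self) -> list[tuple[str, str]]:
        """Break every triple into its (subject, relation) and (object, relation)
        pairs — the edge list fed to relation-agnostic walk embeddings."""
        pairs: list[tuple[str, str]] = []
        for t in self.triples:
            pairs.append((t.subject, t.relation))
            pairs.append((t.object, t.relation))
        return pairs

    def check_adjacency(self) -> bool:
        """Rebuild the adjacency index from the triple set and compare."""
        rebuilt: dict[str, set[tuple[str, str, str]]] = {}
        for key in self._triples:
            s, _, o = key
            rebuilt.setdefault(s, set()).add(key)
            rebuilt.setdefault(o, set()).add(key)
        return rebuilt == {k: v for k, v in self._adjacency.items() if v}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            set(self._triples) == set(other._triples)
            and self.concepts == other.concepts
            and self.registry.names() == other.registry.names()
        )


_COLUMNS = (
    "subject",
    "relation",
    "object",
    "subject_label",
    "subject_tag",
    "object_label",
    "object_tag",
    "provenance",
)


def load_triples(
    path: str | Path, registry: Optional[RelationRegistry] = None
) -> KnowledgeGraph:
    """Load a triple TSV into a :class:`KnowledgeGraph`.

    Rows need >= 3 tab-separated fields; optional columns carry labels,
    semantic tags and provenance. Duplicate rows collapse to one triple.
    Raises :class:`TripleParseError` naming the offending line on malformed
    input; an empty file yields an empty graph.
    """
    graph = KnowledgeGraph(registry.copy() if registry is not None else None)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TripleParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            fields += [""] * (len(_COLUMNS) - len(fields))
            s, r, o, s_label, s_tag, o_label, o_tag, prov = fields[: len(_COLUMNS)]
            if not s or not o:
                raise TripleParseError(
                    f"{path}: line {lineno}: empty subject or object code"
                )
            graph.add_concept(Concept(s, s_label, s_tag))
            graph.add_concept(Concept(o, o_label, o_tag))
            graph.add_triple(SemanticTriple(s, r, o, prov))
    return graph


def save_triples(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write a graph as triple TSV; ``load_triples`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for t in graph.triples:
            s = graph.concept(t.subject)
            o = graph.concept(t.object)
            fh.write(
                "\t".join(
                    (
                        t.subject,
                        t.relation,
                        t.object,
                        s.label,
                        s.semantic_tag,
                        o.label,
                        o.semantic_tag,
                        t.provenance,
                    )
                )
                + "\n"
            )
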