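"""Question codes -> clinical context: expand, retrieve, filter, verbalize.

The retrieval-augmented generation path works in one adjacency hop:

1. **expand** the question's concept codes with their top-k cosine
   neighbors from one or more embedding spaces (an ensemble combined by
   union of neighbor sets);
2. **retrieve** every triple incident to an expanded code from the graph;
3. **filter** to the relation types flagged ``rag_use`` in the registry
   (13 of the 40 default relations), dropping low-value structural links
   like "isa" or "part of";
4. **verbalize** each surviving triple as a human-readable sentence, e.g.
   ``"urinalysis" (procedure) diagnoses "crystalluria" (finding)``.

The resulting context is deduplicated, capped (seed-incident triples
kept first) and rendered into a prompt alongside the question.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .embeddings import EmbeddingSpace, nearest_neighbors
from .kg import KnowledgeGraph, RelationRegistry, SemanticTriple

logger = logging.getLogger(__name__)

__all__ = [
    "RetrievalConfig",
    "RagContext",
    "PromptBundle",
    "expand_codes",
    "retrieve_triples",
    "filter_by_relation",
    "verbalize_triple",
    "build_context",
    "build_prompt",
]


@dataclass
class RetrievalConfig:
    """Context-building knobs: neighbors per seed per space and sentence cap.

    Defaults (k=5, cap=40) keep prompts inside typical backend input
    limits while leaving room for every seed-incident fact on small
    graphs; both are configurable per run.
    """

    k: int = 5
    cap: int = 40
    template_id: str = "v1"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.cap < 0:
            raise ValueError("cap must be >= 0")


@dataclass
class RagContext:
    """Ordered, deduplicated verbalized sentences plus their source triples."""

    sentences: list[str]
    source_triples: list[SemanticTriple]
    stats: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass
class PromptBundle:
    """A rendered prompt: question + choices, optionally preceded by context."""

    question_id: str
    question: str
    choices: dict[str, str]
    context_sentences: list[str]
    prompt: str
    template_id: str


def expand_codes(
    codes: Sequence[str],
    spaces: Iterable[EmbeddingSpace],
    k: int,
) -> list[str]:
    """Seed codes plus the union of their top-k neighbors from each space.

    Seeds come first in their given order; neighbors follow by descending
    best similarity across all (seed, space) pairs, ties broken
    lexicographically. Codes absent from every space stay as seeds and are
    logged. k=0 is the identity on the seed set.
    """
    seeds = list(dict.fromkeys(codes))
    if k == 0:
        return seeds
    seed_set = set(seeds)
    best: dict[str, float] = {}
    spaces = list(spaces)
    for seed in seeds:
        found = False
        for space in spaces:
            if seed not in space:
                continue
            found = True
            for nbr, sim in nearest_neighbors(space, seed, k):
                if nbr in seed_set:
                    continue
                if nbr not in best or sim > best[nbr]:
                    best[nbr] = sim
        if not found and spaces:
            logger.info("code %r absent from all embedding spaces; kept as seed only", seed)
    expansion = sorted(best, key=lambda c: (-best[c], c))
    return seeds + expansion


def retrieve_triples(graph: KnowledgeGraph, codes: Sequence[str]) -> list[SemanticTriple]:
    """Union of incident triples over all codes, deduplicated, stable order."""
    seen: dict[tuple[str, str, str], SemanticTriple] = {}
    for code in codes:
        for t in graph.neighbors(code):
            seen.setdefault(t.key(), t)
    return list(seen.values())


def filter_by_relation(
    triples: Sequence[SemanticTriple], registry: RelationRegistry
) -> list[SemanticTriple]:
    """Keep exactly the triples whose relation is flagged ``rag_use``.

    A pure, order-preserving, idempotent filter. Relations missing from
    the registry drop their triples with a warning.
    """
    out = []
    for t in triples:
        if t.relation not in registry:
            logger.warning("relation %r not in registry; triple dropped", t.relation)
            continue
        if registry[t.relation].rag_use:
            out.append(t)
    return out


def verbalize_triple(triple: SemanticTriple, graph: KnowledgeGraph) -> str:
    """Render one triple as a human-readable clinical sentence.

    Template: ``"<subject label>" (<subject tag>) <relation> "<object label>"
    (<object tag>)`` with the parenthetical omitted when a concept has no
    semantic tag, and the code itself as fallback label.
    """
    s = graph.concept(triple.subject)
    o = graph.concept(triple.object)

    def part(label: str, tag: str) -> str:
        return f'"{label}" ({tag})' if tag else f'"{label}"'

    return (
        f"{part(s.display_label, s.semantic_tag)} {triple.relation} "
        f"{part(o.display_label, o.semantic_tag)}"
    )


def build_context(
    graph: KnowledgeGraph,
    spaces: Iterable[EmbeddingSpace],
    question_codes: Sequence[str],
    config: Optional[RetrievalConfig] = None,
) -> RagContext:
    """Full retrieval pipeline for one question's codes.

    expand -> retrieve -> relation filter -> verbalize -> dedupe -> cap.
    Truncation keeps triples incident to the original question codes ahead
    of neighbor-only triples, since question-specific knowledge is the
    point of the exercise. Empty ``question_codes`` is valid and yields an
    empty context (the native-prompt fallback).
    """
    config = config or RetrievalConfig()
    seeds = list(dict.fromkeys(question_codes))
    if not seeds:
        return RagContext([], [], {"seed_codes": 0, "expanded_codes": 0, "retrieved": 0, "after_filter": 0, "kept": 0})
    expanded = expand_codes(seeds, spaces, config.k)
    retrieved = retrieve_triples(graph, expanded)
    filtered = filter_by_relation(retrieved, graph.registry)

    seed_set = set(seeds)
    seed_incident = [t for t in filtered if t.subject in seed_set or t.object in seed_set]
    rest = [t for t in filtered if not (t.subject in seed_set or t.object in seed_set)]

    sentences: list[str] = []
    sources: list[SemanticTriple] = []
    seen: set[str] = set()
    for t in seed_incident + rest:
        if len(sentences) >= config.cap:
            break
        sentence = verbalize_triple(t, graph)
        if sentence in seen:
            continue
        seen.add(sentence)
        sentences.append(sentence)
        sources.append(t)
    stats = {
        "seed_codes": len(seeds),
        "expanded_codes": len(expanded),
        "retrieved": len(retrieved),
        "after_filter": len(filtered),
        "kept": len(sentences),
    }
    return RagContext(sentences, sources, stats)


_TEMPLATES = {
    "v1": (
        "{context_block}"
        "Question:\n{question}\n\n"
        "{choices_block}\n"
        "Answer with the letter of the single best choice."
    )
}


def build_prompt(
    question: Mapping[str, object] | object,
    context: Optional[RagContext] = None,
    template_id: str = "v1",
) -> PromptBundle:
    """Render the native or RAG form of a question prompt.

    ``question`` needs ``id``, ``stem`` and ``choices`` (letter -> text,
    at least two). The RAG form differs from the native form only by the
    leading clinical-context block; every context sentence appears exactly
    once and the stem appears verbatim.
    """
    if isinstance(question, Mapping):
        qid, stem, choices = question["id"], question["stem"], question["choices"]
    else:
        qid, stem, choices = question.id, question.stem, question.choices
    choices = dict(choices)
    if len(choices) < 2:
        raise ValueError(f"question {qid!r} needs at least 2 choices")
    if template_id not in _TEMPLATES:
        raise ValueError(f"unknown prompt template {template_id!r}")
    sentences = list(context.sentences) if context is not None else []
    if sentences:
        context_block = (
            "Clinical context:\n" + "\n".join(sentences) + "\n\n"
        )
    else:
        context_block = ""
    choices_block = "\n".join(
        f"({letter}) {text}" for letter, text in sorted(choices.items())
    )
    prompt = _TEMPLATES[template_id].format(
        context_block=context_block, question=stem, choices_block=choices_block
    )
    return PromptBundle(
        question_id=str(qid),
        question=str(stem),
        choices={str(k): str(v) for k, v in choices.items()},
        context_sentences=sentences,
        prompt=prompt,
        template_id=template_id,
    )
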