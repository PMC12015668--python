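"""Synthetic worlds: knowledge graphs, lexicons and exams with planted facts.

Real clinical corpora (licensed terminologies, drug-label databases,
licensing-exam questions) cannot ship with a library, so every pipeline
stage is exercised on generated stand-ins instead:

* a typed knowledge graph whose relation frequencies follow the shipped
  registry's corpus-scale mix (so the structural "isa"-type relations
  dominate, exactly as the relation filter expects);
* a lexicon covering every concept label, so the tagger can recover the
  concepts mentioned by a stem;
* an exam in which each question's correct answer is entailed by exactly
  one planted RAG-eligible triple whose subject label appears in the
  stem — making end-to-end retrieval success checkable by construction.

Concept labels are pronounceable invented words, guaranteed unique, so
tagging is unambiguous and collision-free. Everything is reproducible
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .exam import Exclusion, Question, save_exam
from .kg import (
    Concept,
    KnowledgeGraph,
    RelationRegistry,
    SemanticTriple,
    default_registry,
    save_triples,
)
from .retrieval import verbalize_triple
from .tagger import Lexicon, save_lexicon

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_kg",
    "build_lexicon",
    "generate_exam",
    "make_world",
    "write_world",
    "make_curation_manifest",
    "STEP_EXCLUSION_PROFILES",
]

_SEMANTIC_TAGS = ("disorder", "finding", "procedure", "substance", "organism")
_ONSETS = "b bl br d dr f fl g gl k kl kr l m n p pl pr r s sk st t tr v z".split()
_VOWELS = "a e i o u".split()
_CODAS = ["", "n", "r", "l", "x", "s", "m"]


def _invent_label(rng: np.random.Generator, taken: set[str]) -> str:
    """A unique pronounceable pseudo-term, e.g. 'drelozanir'."""
    for _ in range(1000):
        n_syll = int(rng.integers(3, 5))
        word = "".join(
            _ONSETS[int(rng.integers(len(_ONSETS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            + (_CODAS[int(rng.integers(len(_CODAS)))] if s == n_syll - 1 else "")
            for s in range(n_syll)
        )
        if word not in taken:
            taken.add(word)
            return word
    raise RuntimeError("label space exhausted")  # pragma: no cover


def generate_kg(
    n_concepts: int,
    n_triples: int,
    relation_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    registry: Optional[RelationRegistry] = None,
) -> KnowledgeGraph:
    """Random typed triple set with a requested relation mix.

    ``relation_mix`` maps relation name -> weight; the default is
    proportional to the registry's corpus frequency hints. Triples are
    distinct (no multigraph duplicates), self-loop free, and grown from a
    random spanning tree first so the graph has a connected core for
    retrieval tests. Relation frequencies are multinomial around the mix,
    hence within a couple of percent of it for large ``n_triples``.
    """
    if n_concepts < 2:
        raise ValueError("need at least 2 concepts")
    registry = (registry or default_registry()).copy()
    if relation_mix is None:
        relation_mix = {
            r.name: float(r.count_hint or 1) for r in registry
        }
    names = sorted(relation_mix)
    weights = np.array([relation_mix[n] for n in names], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("relation mix weights must be nonnegative with positive sum")
    probs = weights / weights.sum()
    if n_triples > n_concepts * (n_concepts - 1) * len(names):
        raise ValueError("n_triples exceeds the number of distinct possible triples")

    rng = np.random.default_rng(seed)
    graph = KnowledgeGraph(registry)
    taken: set[str] = set()
    codes = [f"C{i:06d}" for i in range(n_concepts)]
    for code in codes:
        label = _invent_label(rng, taken)
        tag = _SEMANTIC_TAGS[int(rng.integers(len(_SEMANTIC_TAGS)))]
        graph.add_concept(Concept(code, label, tag))
    if n_triples == 0:
        return graph

    relations = [names[i] for i in rng.choice(len(names), size=n_triples, p=probs)]
    used = 1
    order = rng.permutation(n_concepts)
    seen: set[tuple[str, str, str]] = set()
    count = 0
    attempts = 0
    max_attempts = 50 * n_triples + 1000
    while count < n_triples and attempts < max_attempts:
        attempts += 1
        rel = relations[count]
        if used < n_concepts and count < n_concepts - 1:
            # spanning-tree phase: attach a fresh concept to the core
            s = codes[order[int(rng.integers(used))]]
            o = codes[order[used]]
            if rng.random() < 0.5:
                s, o = o, s
        else:
            i, j = rng.integers(n_concepts), rng.integers(n_concepts)
            s, o = codes[int(i)], codes[int(j)]
        if s == o or (s, rel, o) in seen:
            continue
        seen.add((s, rel, o))
        graph.add_triple(SemanticTriple(s, rel, o, provenance="synthetic"))
        if used < n_concepts and count < n_concepts - 1:
            used += 1
        count += 1
    if count < n_triples:
        raise RuntimeError("could not place the requested number of distinct triples")
    return graph


def build_lexicon(graph: KnowledgeGraph) -> Lexicon:
    """Lexicon mapping every concept label to its code."""
    lex = Lexicon()
    for code, concept in sorted(graph.concepts.items()):
        if concept.label:
            lex.add(concept.label, code)
    return lex


_STEM_TEMPLATE = (
    "A patient chart from case {case} documents a history of {subject}. "
    "According to the clinical knowledge base, which of the following is most "
    "directly associated with {subject}?"
)


def generate_exam(
    graph: KnowledgeGraph,
    n_questions: int,
    n_choices: int = 5,
    seed: int = 0,
) -> tuple[list[Question], dict[str, str]]:
    """Questions each answerable from one planted RAG-eligible triple.

    Every stem embeds the subject label of a distinct ``rag_use`` triple;
    the correct choice is that triple's object label, distractors are
    labels of concepts with no edge to the subject, and the verbalized
    triple is stored as the question's key sentence. Returns (questions,
    answer key).
    """
    if n_choices < 2 or n_choices > 26:
        raise ValueError("n_choices must be in [2, 26]")
    rag_names = graph.registry.rag_relations()
    candidates = [t for t in graph.triples if t.relation in rag_names]
    if len(candidates) < n_questions:
        raise ValueError(
            f"graph has {len(candidates)} RAG-eligible triples; need {n_questions}"
        )
    rng = np.random.default_rng(seed)
    picked_idx = rng.choice(len(candidates), size=n_questions, replace=False)
    letters = [chr(ord("A") + i) for i in range(n_choices)]
    all_codes = sorted(graph.concepts)
    questions: list[Question] = []
    key: dict[str, str] = {}
    for qnum, ti in enumerate(sorted(int(i) for i in picked_idx)):
        triple = candidates[ti]
        subj = graph.concept(triple.subject)
        obj = graph.concept(triple.object)
        adjacent = {triple.subject, triple.object}
        for t in graph.neighbors(triple.subject):
            adjacent.add(t.subject)
            adjacent.add(t.object)
        pool = [c for c in all_codes if c not in adjacent]
        if len(pool) < n_choices - 1:
            raise ValueError("graph too dense to draw unrelated distractors")
        distractor_codes = [
            pool[int(i)] for i in rng.choice(len(pool), size=n_choices - 1, replace=False)
        ]
        choice_labels = [obj.display_label] + [
            graph.concept(c).display_label for c in distractor_codes
        ]
        positions = rng.permutation(n_choices)
        choices = {letters[int(positions[i])]: lab for i, lab in enumerate(choice_labels)}
        key_letter = letters[int(positions[0])]
        qid = f"q{qnum:04d}"
        questions.append(
            Question(
                id=qid,
                stem=_STEM_TEMPLATE.format(case=qnum + 1, subject=subj.display_label),
                choices=choices,
                key=key_letter,
                key_sentence=verbalize_triple(triple, graph),
            )
        )
        key[qid] = key_letter
    return questions, key


@dataclass
class WorldConfig:
    """Size and shape of a synthetic world.

    Defaults give a desk-scale corpus (300 concepts, 900 triples — mean
    degree 6, like a sparse clinical subgraph) and a 100-question exam
    with 5 choices, the size at which the paired comparison is run.
    """

    n_concepts: int = 300
    n_triples: int = 900
    n_questions: int = 100
    n_choices: int = 5
    relation_mix: Optional[dict[str, float]] = None


@dataclass
class SyntheticWorld:
    graph: KnowledgeGraph
    lexicon: Lexicon
    exam: list[Question]
    key: dict[str, str]
    seed: int
    config: WorldConfig = field(default_factory=WorldConfig)


def make_world(config: Optional[WorldConfig] = None, seed: int = 0) -> SyntheticWorld:
    """Complete reproducible fixture: graph + lexicon + planted exam."""
    config = config or WorldConfig()
    graph = generate_kg(
        config.n_concepts, config.n_triples, config.relation_mix, seed=seed
    )
    lexicon = build_lexicon(graph)
    exam, key = generate_exam(
        graph, config.n_questions, config.n_choices, seed=seed + 1
    )
    return SyntheticWorld(graph, lexicon, exam, key, seed, config)


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write triples.tsv, lexicon.tsv and exam.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "triples": out / "triples.tsv",
        "lexicon": out / "lexicon.tsv",
        "exam": out / "exam.json",
    }
    save_triples(world.graph, paths["triples"])
    save_lexicon(world.lexicon, paths["lexicon"])
    save_exam(world.exam, paths["exam"])
    return paths


# Text-only curation profiles of the three licensing-exam sample sets the
# evaluation emulates: (total questions, visual exclusions by reason,
# nonvisual exclusions by reason).
STEP_EXCLUSION_PROFILES: dict[int, dict] = {
    1: {
        "total": 119,
        "visual": {
            "photograph": 8,
            "graph": 5,
            "photomicrograph": 4,
            "multipart answer with directional arrows": 3,
            "radiograph": 2,
            "diagram": 2,
            "CT scan": 1,
            "MRI": 1,
            "Doppler image": 1,
            "bar graph": 1,
            "ultrasonography": 1,
        },
        "nonvisual": {"multipart answer not conducive to a text file format": 3},
    },
    2: {
        "total": 120,
        "visual": {
            "photograph": 6,
            "radiograph": 4,
            "cardiac rhythm strip": 1,
            "fetal heart tracing": 1,
            "hysterosalpingography": 1,
            "stool smear": 1,
        },
        "nonvisual": {"complex table not conducive to a text file format": 3},
    },
    3: {
        "total": 137,
        "visual": {
            "radiograph": 5,
            "photograph": 4,
            "family pedigree": 1,
            "ECG component": 1,
        },
        "nonvisual": {
            "complex 2-page pharmaceutical advertisement": 2,
            "complex table not conducive to a text file format": 1,
        },
    },
}


def make_curation_manifest(step: int = 1, seed: int = 0) -> list[Question]:
    """Synthetic exam manifest matching one step's exclusion profile.

    Exclusion annotations are scattered over seeded-random positions; the
    curation rule engine must recover exactly the profile's kept count.
    """
    profile = STEP_EXCLUSION_PROFILES[step]
    exclusions: list[Optional[Exclusion]] = []
    for category in ("visual", "nonvisual"):
        for reason, count in profile[category].items():
            exclusions.extend([Exclusion(category, reason)] * count)
    exclusions.extend([None] * (profile["total"] - len(exclusions)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(exclusions))
    questions = []
    for i, pos in enumerate(order):
        questions.append(
            Question(
                id=f"s{step}-q{i:03d}",
                stem=f"Synthetic manifest question {i} for step {step}.",
                choices={"A": "first option", "B": "second option"},
                key="A",
                exclusion=exclusions[int(pos)],
            )
        )
    return questions
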