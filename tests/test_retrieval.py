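"""Code expansion, triple retrieval, relation filtering, verbalization, prompts."""

import json

import numpy as np
import pytest

from scai.embeddings import EmbeddingSpace
from scai.kg import Concept, KnowledgeGraph, SemanticTriple, default_registry
from scai.retrieval import (
    RagContext,
    RetrievalConfig,
    build_context,
    build_prompt,
    expand_codes,
    filter_by_relation,
    retrieve_triples,
    verbalize_triple,
)


def _space(vectors, dim=4):
    return EmbeddingSpace(
        dim=dim, method="walk",
        vectors={k: np.asarray(v, float) for k, v in vectors.items()},
    )


@pytest.fixture
def clinical_graph():
    g = KnowledgeGraph()
    g.add_concept(Concept("C_UA", "urinalysis", "procedure"))
    g.add_concept(Concept("C_CRY", "crystalluria", "finding"))
    g.add_concept(Concept("C_PROT", "nephrotic range proteinuria", "finding"))
    g.add_concept(Concept("C_OC", "uses OC (oral contraceptive)", ""))
    g.add_concept(Concept("C_AMEN", "amenorrhea", "finding"))
    g.add_triple(SemanticTriple("C_UA", "diagnoses", "C_CRY"))
    g.add_triple(SemanticTriple("C_UA", "diagnoses", "C_PROT"))
    g.add_triple(SemanticTriple("C_OC", "causes", "C_AMEN"))
    g.add_triple(SemanticTriple("C_UA", "isa", "C_PROT"))  # filtered out
    return g


# -- expand ------------------------------------------------------------------


def test_expand_k0_identity():
    sp = _space({"a": [1, 0, 0, 0], "b": [0, 1, 0, 0]})
    assert expand_codes(["b", "a", "b"], [sp], k=0) == ["b", "a"]


def test_expand_duplicate_vector_ranked_first():
    sp = _space({"seed": [1, 0, 0, 0], "twin": [2, 0, 0, 0], "far": [0, 1, 0, 0]})
    got = expand_codes(["seed"], [sp], k=2)
    assert got[0] == "seed" and got[1] == "twin"


def test_expand_union_bound_two_spaces():
    rng = np.random.default_rng(0)
    codes = [f"c{i}" for i in range(30)]
    sp1 = _space({c: rng.normal(size=4) for c in codes})
    sp2 = _space({c: rng.normal(size=4) for c in codes})
    seeds = ["c0", "c1"]
    k = 3
    got = expand_codes(seeds, [sp1, sp2], k=k)
    assert got[: len(seeds)] == seeds
    assert len(got) == len(set(got))
    assert len(got) <= len(seeds) + 2 * k * len(seeds)


def test_expand_absent_code_kept_as_seed():
    sp = _space({"known": [1, 0, 0, 0], "other": [0, 1, 0, 0]})
    got = expand_codes(["ghost"], [sp], k=2)
    assert got == ["ghost"]


# -- retrieve ----------------------------------------------------------------


def test_retrieve_absent_codes_empty(clinical_graph):
    assert retrieve_triples(clinical_graph, ["nope", "also-nope"]) == []


def test_retrieve_single_incident_triple(fig_graph):
    got = retrieve_triples(fig_graph, ["C323"])
    assert [t.key() for t in got] == [("C323", "treats", "C233604007")]


def test_retrieve_star_center_gets_all_spokes():
    g = KnowledgeGraph()
    for o in ("S1", "S2", "S3"):
        g.add_triple(SemanticTriple("hub", "treats", o))
    assert len(retrieve_triples(g, ["hub"])) == 3
    # dedupe across overlapping query codes
    assert len(retrieve_triples(g, ["hub", "S1"])) == 3


# -- filter ------------------------------------------------------------------


def test_filter_keeps_rag_relations_only():
    reg = default_registry()
    isa = [SemanticTriple("A", "isa", "B")]
    treats = [SemanticTriple("A", "treats", "B")]
    assert filter_by_relation(isa, reg) == []
    assert filter_by_relation(treats, reg) == treats


def test_filter_probe_one_triple_per_relation():
    reg = default_registry()
    probe = [
        SemanticTriple(f"S{i}", rel.name, f"O{i}") for i, rel in enumerate(reg)
    ]
    assert len(probe) == 40
    kept = filter_by_relation(probe, reg)
    assert len(kept) == 13
    assert {t.relation for t in kept} == reg.rag_relations()


def test_filter_pure_idempotent_order_preserving():
    reg = default_registry()
    rng = np.random.default_rng(1)
    rels = sorted(reg.names())
    triples = [
        SemanticTriple(f"S{i}", rels[int(rng.integers(len(rels)))], f"O{i}")
        for i in range(50)
    ]
    once = filter_by_relation(triples, reg)
    assert filter_by_relation(once, reg) == once
    assert all(t in triples for t in once)
    positions = [triples.index(t) for t in once]
    assert positions == sorted(positions)


def test_filter_unregistered_relation_dropped(caplog):
    reg = default_registry()
    import logging

    with caplog.at_level(logging.WARNING, logger="scai.retrieval"):
        got = filter_by_relation([SemanticTriple("A", "mystery link", "B")], reg)
    assert got == []
    assert any("mystery link" in r.message for r in caplog.records)


# -- verbalize ---------------------------------------------------------------


def test_verbalize_with_tags(clinical_graph):
    t = SemanticTriple("C_UA", "diagnoses", "C_CRY")
    assert (
        verbalize_triple(t, clinical_graph)
        == '"urinalysis" (procedure) diagnoses "crystalluria" (finding)'
    )


def test_verbalize_omits_empty_tag(clinical_graph):
    t = SemanticTriple("C_OC", "causes", "C_AMEN")
    assert (
        verbalize_triple(t, clinical_graph)
        == '"uses OC (oral contraceptive)" causes "amenorrhea" (finding)'
    )


def test_verbalize_falls_back_to_codes():
    g = KnowledgeGraph()
    g.add_triple(SemanticTriple("C1", "treats", "C2"))
    assert verbalize_triple(g.triples[0], g) == '"C1" treats "C2"'


# -- build_context -----------------------------------------------------------


def test_context_empty_codes(clinical_graph):
    ctx = build_context(clinical_graph, [], [], RetrievalConfig())
    assert ctx.sentences == [] and ctx.stats["kept"] == 0


def test_context_single_path(clinical_graph):
    ctx = build_context(clinical_graph, [], ["C_OC"], RetrievalConfig(k=0))
    assert ctx.sentences == ['"uses OC (oral contraceptive)" causes "amenorrhea" (finding)']
    assert ctx.source_triples[0].key() == ("C_OC", "causes", "C_AMEN")


def test_context_filters_structural_relations(clinical_graph):
    ctx = build_context(clinical_graph, [], ["C_UA"], RetrievalConfig(k=0))
    assert all(t.relation == "diagnoses" for t in ctx.source_triples)
    assert ctx.stats["retrieved"] == 3 and ctx.stats["after_filter"] == 2


def test_context_cap_prefers_seed_incident():
    g = KnowledgeGraph()
    # seed has 10 rag-eligible triples; its neighbor n0 has 50 more
    for i in range(10):
        g.add_triple(SemanticTriple("seed", "treats", f"n{i}"))
    for i in range(50):
        g.add_triple(SemanticTriple("n0", "causes", f"m{i}"))
    sp = _space({"seed": [1, 0, 0, 0], "n0": [1, 0.1, 0, 0]})
    ctx = build_context(g, [sp], ["seed"], RetrievalConfig(k=1, cap=5))
    assert len(ctx.sentences) == 5
    assert all("seed" in (t.subject, t.object) for t in ctx.source_triples)
    # uncapped: every retrieved rag triple appears
    full = build_context(g, [sp], ["seed"], RetrievalConfig(k=1, cap=1000))
    assert len(full.sentences) == 60


def test_context_monotone_in_k():
    g = KnowledgeGraph()
    for i in range(4):
        g.add_triple(SemanticTriple("seed", "treats", f"n{i}"))
    g.add_triple(SemanticTriple("n0", "causes", "m0"))
    sp = _space({"seed": [1, 0, 0, 0], "n0": [0.9, 0.1, 0, 0], "m0": [0, 1, 0, 0]})
    small = build_context(g, [sp], ["seed"], RetrievalConfig(k=0, cap=1000))
    big = build_context(g, [sp], ["seed"], RetrievalConfig(k=2, cap=1000))
    assert set(small.sentences) <= set(big.sentences)


def test_context_deterministic(clinical_graph):
    cfg = RetrievalConfig(k=0)
    a = build_context(clinical_graph, [], ["C_UA", "C_OC"], cfg)
    b = build_context(clinical_graph, [], ["C_UA", "C_OC"], cfg)
    assert json.dumps(a.sentences) == json.dumps(b.sentences)
    assert a.stats == b.stats


# -- prompts -----------------------------------------------------------------

_QUESTION = {
    "id": "q1",
    "stem": "Urinalysis and urine culture are normal. Which is the next step?",
    "choices": {"A": "Recommend behavioral therapy", "B": "Reassure the patient"},
}


def test_prompt_native_equals_empty_context():
    native = build_prompt(_QUESTION)
    empty = build_prompt(_QUESTION, RagContext([], []))
    assert native.prompt == empty.prompt
    assert _QUESTION["stem"] in native.prompt


def test_prompt_contains_each_sentence_once(clinical_graph):
    ctx = build_context(clinical_graph, [], ["C_UA", "C_OC"], RetrievalConfig(k=0))
    bundle = build_prompt(_QUESTION, ctx)
    assert '"urinalysis" (procedure) diagnoses "crystalluria" (finding)' in bundle.prompt
    for sentence in ctx.sentences:
        assert bundle.prompt.count(sentence) == 1
    assert bundle.prompt.count(_QUESTION["stem"]) == 1
    # RAG and native prompts differ only by the context block
    native = build_prompt(_QUESTION)
    assert bundle.prompt.endswith(native.prompt)


def test_prompt_requires_two_choices():
    with pytest.raises(ValueError, match="choices"):
        build_prompt({"id": "q", "stem": "s", "choices": {"A": "only"}})
    with pytest.raises(ValueError, match="template"):
        build_prompt(_QUESTION, template_id="v999")
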