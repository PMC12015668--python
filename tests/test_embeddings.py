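"""Walk generation, skip-gram, TransE/RotatE scoring and training, cosine search."""

import numpy as np
import pytest
from scipy import stats

from scai.embeddings import (
    EmbeddingSpace,
    TrainingConfig,
    cosine_similarity,
    generate_walks,
    link_prediction_hits,
    load_space,
    nearest_neighbors,
    rotate_score,
    save_space,
    skipgram_train,
    train_kge,
    transe_score,
)
from scai.kg import KnowledgeGraph, RelationRegistry, RelationType, SemanticTriple


def _space(vectors, dim, method="transe", relations=None):
    return EmbeddingSpace(
        dim=dim,
        method=method,
        vectors={k: np.asarray(v, float) for k, v in vectors.items()},
        relation_vectors={k: np.asarray(v, float) for k, v in (relations or {}).items()},
    )


def _chain_graph(n, relation="treats"):
    g = KnowledgeGraph(RelationRegistry([RelationType(relation, True)]))
    for i in range(n - 1):
        g.add_triple(SemanticTriple(f"N{i}", relation, f"N{i + 1}"))
    return g


def _two_cliques(size=5):
    """Two cliques joined by nothing; distinct relations per clique so the
    relation tokens in the pair graph do not bridge the communities."""
    g = KnowledgeGraph(
        RelationRegistry([RelationType("treats", True), RelationType("causes", True)])
    )
    for rel, prefix in (("treats", "A"), ("causes", "B")):
        nodes = [f"{prefix}{i}" for i in range(size)]
        for i in range(size):
            for j in range(i + 1, size):
                g.add_triple(SemanticTriple(nodes[i], rel, nodes[j]))
    return g


# -- cosine & neighbors ------------------------------------------------------


def test_cosine_basic_identities():
    x = np.array([1.0, 2.0, 3.0])
    assert cosine_similarity(x, x) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity(x, -x) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="zero vector"):
        cosine_similarity(x, np.zeros(3))


def test_nearest_neighbors_caps_and_duplicates():
    sp = _space({"a": [1, 0], "b": [0, 1], "dup": [2, 0]}, 2)
    got = nearest_neighbors(sp, "a", k=5)
    assert len(got) == 2
    assert got[0] == ("dup", pytest.approx(1.0))
    with pytest.raises(KeyError):
        nearest_neighbors(sp, "missing", 1)
    with pytest.raises(ValueError):
        nearest_neighbors(sp, "a", 0)


def test_nearest_neighbors_equals_bruteforce_scan():
    rng = np.random.default_rng(42)
    codes = [f"c{i:03d}" for i in range(200)]
    sp = _space({c: rng.normal(size=128) for c in codes}, 128)
    query = "c007"
    got = nearest_neighbors(sp, query, k=10)
    brute = sorted(
        (
            (c, cosine_similarity(sp.vectors[query], sp.vectors[c]))
            for c in codes
            if c != query
        ),
        key=lambda t: (-t[1], t[0]),
    )[:10]
    assert [c for c, _ in got] == [c for c, _ in brute]
    assert np.allclose([s for _, s in got], [s for _, s in brute])


# -- scoring -----------------------------------------------------------------


def test_transe_score_constructed_identity():
    r = np.array([1.0, -1.0, 0.5])
    s = np.array([0.2, 0.3, 0.4])
    sp = _space({"s": s, "o": s + r}, 3, relations={"treats": r})
    assert transe_score(sp, "s", "treats", "o") == pytest.approx(0.0)


def test_transe_translation_invariance():
    rng = np.random.default_rng(0)
    vs, vo, vr = rng.normal(size=(3, 8))
    shift = rng.normal(size=8)
    a = _space({"s": vs, "o": vo}, 8, relations={"r": vr})
    b = _space({"s": vs + shift, "o": vo + shift}, 8, relations={"r": vr})
    assert transe_score(a, "s", "r", "o") == pytest.approx(transe_score(b, "s", "r", "o"))


def test_transe_score_equals_norm_oracle():
    rng = np.random.default_rng(1)
    vs, vo, vr = rng.normal(size=(3, 16))
    sp = _space({"s": vs, "o": vo}, 16, relations={"r": vr})
    expected = -np.sqrt(np.sum((vs + vr - vo) ** 2))
    assert transe_score(sp, "s", "r", "o") == pytest.approx(expected)
    with pytest.raises(KeyError, match="missing"):
        transe_score(sp, "missing", "r", "o")


def _interleave(c):
    out = np.empty(c.size * 2)
    out[0::2], out[1::2] = c.real, c.imag
    return out


def test_rotate_identity_rotation():
    rng = np.random.default_rng(2)
    s = rng.normal(size=4) + 1j * rng.normal(size=4)
    identity = np.ones(4, dtype=complex)  # zero phases
    sp = _space(
        {"s": _interleave(s), "o": _interleave(s)}, 8, method="rotate",
        relations={"r": _interleave(identity)},
    )
    assert rotate_score(sp, "s", "r", "o") == pytest.approx(0.0)


def test_rotate_preserves_entity_norms():
    rng = np.random.default_rng(3)
    s = rng.normal(size=8) + 1j * rng.normal(size=8)
    phases = np.exp(1j * rng.uniform(0, 2 * np.pi, 8))
    assert np.linalg.norm(s * phases) == pytest.approx(np.linalg.norm(s))


def test_rotate_score_equals_complex_oracle():
    rng = np.random.default_rng(4)
    s = rng.normal(size=8) + 1j * rng.normal(size=8)
    o = rng.normal(size=8) + 1j * rng.normal(size=8)
    phases = np.exp(1j * rng.uniform(0, 2 * np.pi, 8))
    sp = _space(
        {"s": _interleave(s), "o": _interleave(o)}, 16, method="rotate",
        relations={"r": _interleave(phases)},
    )
    assert rotate_score(sp, "s", "r", "o") == pytest.approx(
        -np.linalg.norm(s * phases - o)
    )


def test_rotate_rejects_nonunit_modulus():
    with pytest.raises(ValueError, match="modulus"):
        _space(
            {"s": [1.0, 0.0]}, 2, method="rotate", relations={"r": [2.0, 0.0]}
        )


# -- walks -------------------------------------------------------------------


def test_isolated_node_walks_are_singletons():
    g = KnowledgeGraph()
    g.ensure_concept("lonely")
    cfg = TrainingConfig(dim=8, walks_per_node=3, walk_length=5, seed=0)
    walks = generate_walks(g, cfg)
    assert walks == [["lonely"]] * 3


def test_path_graph_forced_moves():
    # one triple => pair graph A--treats--B; from A every step alternates
    g = KnowledgeGraph(RelationRegistry([RelationType("treats", True)]))
    g.add_triple(SemanticTriple("A", "treats", "B"))
    cfg = TrainingConfig(dim=8, walks_per_node=2, walk_length=6, p=1, q=1, seed=0)
    for walk in generate_walks(g, cfg):
        for a, b in zip(walk, walk[1:]):
            assert {a, b} != {a}  # always moves
            assert b in ("A", "B", "treats")


def test_walks_reproducible_at_fixed_seed():
    g = _chain_graph(5)
    cfg = TrainingConfig(dim=8, walks_per_node=4, walk_length=8, seed=9)
    assert generate_walks(g, cfg) == generate_walks(g, cfg)
    cfg2 = TrainingConfig(dim=8, walks_per_node=4, walk_length=8, seed=10)
    assert generate_walks(g, cfg) != generate_walks(g, cfg2)


def test_uniform_bias_matches_deepwalk_frequencies():
    """p = q = 1 must reduce to uniform next-step sampling (chi-square)."""
    g = _chain_graph(4)  # pair graph: chain + relation hub 'treats'
    cfg = TrainingConfig(
        dim=8, walks_per_node=150, walk_length=40, p=1.0, q=1.0, seed=13
    )
    walks = generate_walks(g, cfg)
    # count transitions out of the relation hub, which links all 4 nodes
    counts = {}
    for walk in walks:
        for a, b in zip(walk, walk[1:]):
            if a == "treats":
                counts[b] = counts.get(b, 0) + 1
    observed = np.array([counts.get(f"N{i}", 0) for i in range(4)])
    assert observed.sum() > 10_000
    _, p_value = stats.chisquare(observed)
    assert p_value > 0.01


def test_cooccurrence_pairs_join_walk_graph():
    g = KnowledgeGraph()
    g.ensure_concept("X")
    g.ensure_concept("Y")
    cfg = TrainingConfig(dim=8, walks_per_node=1, walk_length=4, seed=0)
    walks = generate_walks(g, cfg, cooccurrence=[("X", "Y")])
    assert any(len(w) > 1 for w in walks)


# -- skip-gram ---------------------------------------------------------------


@pytest.mark.parametrize("dim", [128, 512])
def test_skipgram_separates_cliques(dim):
    g = _two_cliques()
    cfg = TrainingConfig(
        dim=dim, epochs=6, walk_length=10, walks_per_node=5, window=3, seed=3
    )
    walks = generate_walks(g, cfg)
    sp = skipgram_train(walks, cfg, relation_names=g.registry.names())
    assert sp.losses[-1] < sp.losses[0]
    a = [c for c in sp.vectors if c.startswith("A")]
    b = [c for c in sp.vectors if c.startswith("B")]
    within = np.mean(
        [cosine_similarity(sp.vectors[x], sp.vectors[y]) for x in a for y in a if x < y]
        + [cosine_similarity(sp.vectors[x], sp.vectors[y]) for x in b for y in b if x < y]
    )
    cross = np.mean(
        [cosine_similarity(sp.vectors[x], sp.vectors[y]) for x in a for y in b]
    )
    assert within > cross
    # relation tokens trained but kept out of the entity table
    assert set(sp.relation_vectors) == {"treats", "causes"}


def test_skipgram_deterministic():
    g = _two_cliques(3)
    cfg = TrainingConfig(dim=16, epochs=3, walk_length=8, walks_per_node=3, seed=5)
    walks = generate_walks(g, cfg)
    s1 = skipgram_train(walks, cfg)
    s2 = skipgram_train(walks, cfg)
    for code in s1.vectors:
        assert np.array_equal(s1.vectors[code], s2.vectors[code])


def test_skipgram_tiny_vocab_rejected():
    cfg = TrainingConfig(dim=8, seed=0)
    with pytest.raises(ValueError, match="vocabulary"):
        skipgram_train([["only"]], cfg)


# -- KGE training ------------------------------------------------------------


def _planted_transe_graph(n_pairs=15):
    g = KnowledgeGraph(RelationRegistry([RelationType("treats", True)]))
    for i in range(n_pairs):
        g.add_triple(SemanticTriple(f"H{i:02d}", "treats", f"T{i:02d}"))
    return g


def test_kge_unknown_method():
    with pytest.raises(ValueError, match="unknown KGE method"):
        train_kge(_planted_transe_graph(2), "distmult", TrainingConfig(dim=8))


@pytest.mark.parametrize("method", ["transe", "rotate"])
def test_kge_recovers_planted_links(method):
    g = _planted_transe_graph(15)  # 30 entities
    cfg = TrainingConfig(dim=32, epochs=200, learning_rate=0.05, margin=2.0, seed=4)
    sp = train_kge(g, method, cfg)
    hits = link_prediction_hits(sp, g, k=3)
    chance = 3 / 29  # 3 of the 29 candidate tails under random ranking
    assert hits > 2 * chance


def test_kge_single_triple_ranks_true_tail_first():
    g = KnowledgeGraph(RelationRegistry([RelationType("treats", True)]))
    g.add_triple(SemanticTriple("A", "treats", "B"))
    sp = train_kge(g, "transe", TrainingConfig(dim=8, epochs=50, seed=1))
    assert link_prediction_hits(sp, g, k=1) == 1.0


def test_kge_deterministic():
    g = _planted_transe_graph(4)
    cfg = TrainingConfig(dim=16, epochs=10, seed=8)
    s1 = train_kge(g, "transe", cfg)
    s2 = train_kge(g, "transe", cfg)
    for code in s1.vectors:
        assert np.array_equal(s1.vectors[code], s2.vectors[code])
    r1 = train_kge(g, "rotate", cfg)
    mods = np.abs(r1.relation_vectors["treats"][0::2] + 1j * r1.relation_vectors["treats"][1::2])
    assert np.allclose(mods, 1.0, atol=1e-9)


# -- serialization -----------------------------------------------------------


def test_space_roundtrip(tmp_path):
    g = _planted_transe_graph(3)
    sp = train_kge(g, "transe", TrainingConfig(dim=8, epochs=5, seed=2))
    path = tmp_path / "transe_d8.tsv"
    save_space(sp, path)
    sp2 = load_space(path)
    assert sp2.method == "transe" and sp2.dim == 8 and sp2.seed == 2
    for code in sp.vectors:
        assert np.array_equal(sp.vectors[code], sp2.vectors[code])
    for rel in sp.relation_vectors:
        assert np.allclose(sp.relation_vectors[rel], sp2.relation_vectors[rel])
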