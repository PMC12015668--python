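"""Graph and knowledge-graph embeddings over clinical semantic triples.

Two complementary families are trained from the same knowledge graph:

* **walk** — relation-agnostic graph embeddings: biased second-order random
  walks (return parameter ``p``, in-out parameter ``q``; ``p = q = 1``
  reduces to uniform DeepWalk-style walks) over the undirected pair graph
  built from deconstructed triples (code--relation incidence) plus optional
  sentence co-occurrence pairs, followed by skip-gram with negative
  sampling.
* **transe / rotate** — knowledge-graph embeddings scoring whole
  subject-relation-object triples. TransE models a relation as a vector
  translation, score ``-‖v_s + v_r - v_o‖₂``; RotatE models it as an
  elementwise rotation in the complex plane, score ``-‖v_s ∘ v_r - v_o‖``
  with every relation element of unit modulus. Both are trained with a
  margin-based ranking loss against uniformly corrupted triples
  (head or tail replaced with probability 1/2).

Everything is plain seeded-numpy SGD, bit-reproducible at a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .kg import KnowledgeGraph

__all__ = [
    "TrainingConfig",
    "EmbeddingSpace",
    "cosine_similarity",
    "nearest_neighbors",
    "generate_walks",
    "skipgram_train",
    "transe_score",
    "rotate_score",
    "train_kge",
    "link_prediction_hits",
    "save_space",
    "load_space",
]

_ROTATE_TOL = 1e-6


@dataclass
class TrainingConfig:
    """Hyperparameters shared by the walk and KGE trainers.

    ``dim`` is the embedding dimensionality d (128/256/512 supported; 512
    default as the strongest setting). ``p`` and ``q`` are the walk return
    and in-out bias parameters; 1/1 gives uniform walks. ``margin`` is the
    ranking-loss margin used by TransE/RotatE.
    """

    dim: int = 512
    epochs: int = 30
    learning_rate: float = 0.05
    negative: int = 5
    margin: float = 1.0
    walk_length: int = 20
    walks_per_node: int = 10
    window: int = 5
    p: float = 1.0
    q: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dim",
            "epochs",
            "learning_rate",
            "negative",
            "margin",
            "walk_length",
            "walks_per_node",
            "window",
            "p",
            "q",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"TrainingConfig.{name} must be positive")


@dataclass
class EmbeddingSpace:
    """code -> d-vector map with cosine search.

    For ``method='rotate'`` entity vectors are complex vectors of length
    d/2 stored as interleaved (re, im) reals, and relation vectors are
    unit-modulus phase vectors stored the same way.
    """

    dim: int
    method: str
    vectors: dict[str, np.ndarray]
    relation_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    losses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("walk", "transe", "rotate"):
            raise ValueError(f"unknown embedding method {self.method!r}")
        for name, v in list(self.vectors.items()) + list(self.relation_vectors.items()):
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {name!r} has shape {v.shape}, want ({self.dim},)")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"vector for {name!r} has non-finite entries")
        if self.method == "rotate":
            if self.dim % 2:
                raise ValueError("rotate requires an even dimension")
            for name, v in self.relation_vectors.items():
                mod = np.abs(_as_complex(np.asarray(v, dtype=float)))
                if np.any(np.abs(mod - 1.0) > _ROTATE_TOL):
                    raise ValueError(
                        f"rotate relation {name!r} has non-unit modulus elements"
                    )

    def __contains__(self, code: str) -> bool:
        return code in self.vectors

    def vector(self, code: str) -> np.ndarray:
        try:
            return self.vectors[code]
        except KeyError:
            raise KeyError(f"code {code!r} not in embedding space") from None

    def relation_vector(self, name: str) -> np.ndarray:
        try:
            return self.relation_vectors[name]
        except KeyError:
            raise KeyError(f"relation {name!r} not in embedding space") from None


def _as_complex(v: np.ndarray) -> np.ndarray:
    return v[0::2] + 1j * v[1::2]


def _from_complex(c: np.ndarray) -> np.ndarray:
    out = np.empty(c.size * 2, dtype=float)
    out[0::2] = c.real
    out[1::2] = c.imag
    return out


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """⟨x,y⟩ / (‖x‖·‖y‖); undefined (error) for a zero vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def nearest_neighbors(
    space: EmbeddingSpace, code: str, k: int
) -> list[tuple[str, float]]:
    """The k codes most cosine-similar to ``code`` (query excluded).

    Exhaustive scan; descending similarity, ties broken lexicographically
    by code; capped at the number of available codes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    query = space.vector(code)
    codes = sorted(c for c in space.vectors if c != code)
    if not codes:
        return []
    mat = np.stack([space.vectors[c] for c in codes])
    norms = np.linalg.norm(mat, axis=1)
    qn = np.linalg.norm(query)
    if qn == 0.0 or np.any(norms == 0.0):
        raise ValueError("cosine similarity is undefined for a zero vector")
    sims = mat @ query / (norms * qn)
    order = sorted(range(len(codes)), key=lambda i: (-sims[i], codes[i]))
    return [(codes[i], float(sims[i])) for i in order[:k]]


# ---------------------------------------------------------------------------
# walk-based graph embeddings
# ---------------------------------------------------------------------------


def build_pair_graph(
    graph: KnowledgeGraph,
    cooccurrence: Optional[Iterable[tuple[str, str]]] = None,
) -> dict[str, list[str]]:
    """Undirected adjacency over codes and relation tokens.

    Edges come from the deconstructed triples (each triple contributes
    subject--relation and object--relation edges) plus any sentence-level
    code co-occurrence pairs. Neighbor lists are sorted for determinism.
    """
    adj: dict[str, set[str]] = {}
    for a, b in graph.deconstruct():
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    for code in graph.concepts:
        adj.setdefault(code, set())
    if cooccurrence is not None:
        for a, b in cooccurrence:
            if a == b:
                continue
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    return {node: sorted(nbrs) for node, nbrs in sorted(adj.items())}


def generate_walks(
    graph: KnowledgeGraph,
    config: TrainingConfig,
    cooccurrence: Optional[Iterable[tuple[str, str]]] = None,
) -> list[list[str]]:
    """Biased second-order random walks over the pair graph.

    The next step from ``cur`` given previous node ``prev`` is sampled with
    unnormalized weight 1/p to return to ``prev``, 1 to move to a common
    neighbor of ``prev``, and 1/q to move outward; with p = q = 1 this is
    exactly a uniform (DeepWalk) walk. Isolated nodes yield length-1 walks.
    """
    if len(graph.concepts) == 0:
        raise ValueError("cannot walk an empty graph")
    adj = build_pair_graph(graph, cooccurrence)
    neighbor_sets = {node: set(nbrs) for node, nbrs in adj.items()}
    rng = np.random.default_rng(config.seed)
    walks: list[list[str]] = []
    nodes = list(adj)
    for _ in range(config.walks_per_node):
        for start in nodes:
            walk = [start]
            while len(walk) < config.walk_length:
                cur = walk[-1]
                nbrs = adj[cur]
                if not nbrs:
                    break
                if len(walk) == 1:
                    nxt = nbrs[int(rng.integers(len(nbrs)))]
                else:
                    prev = walk[-2]
                    prev_nbrs = neighbor_sets[prev]
                    weights = np.array(
                        [
                            1.0 / config.p
                            if x == prev
                            else (1.0 if x in prev_nbrs else 1.0 / config.q)
                            for x in nbrs
                        ]
                    )
                    weights /= weights.sum()
                    nxt = nbrs[int(rng.choice(len(nbrs), p=weights))]
                walk.append(nxt)
            walks.append(walk)
    return walks


def skipgram_train(
    walks: Sequence[Sequence[str]],
    config: TrainingConfig,
    relation_names: Iterable[str] = (),
) -> EmbeddingSpace:
    """Skip-gram with negative sampling over walk sequences.

    Plain SGD at a fixed learning rate; the per-epoch mean negative
    log-likelihood is recorded in ``space.losses``. Tokens named in
    ``relation_names`` land in ``relation_vectors`` rather than the entity
    map, so cosine search never surfaces relation tokens as neighbors.
    """
    if not walks:
        raise ValueError("no walks to train on")
    relation_names = frozenset(relation_names)
    vocab = sorted({tok for walk in walks for tok in walk})
    if len(vocab) < 2:
        raise ValueError("vocabulary must contain at least 2 tokens for negative sampling")
    index = {tok: i for i, tok in enumerate(vocab)}
    counts = np.zeros(len(vocab))
    for walk in walks:
        for tok in walk:
            counts[index[tok]] += 1
    neg_probs = counts**0.75
    neg_probs /= neg_probs.sum()

    rng = np.random.default_rng(config.seed)
    dim = config.dim
    W = (rng.random((len(vocab), dim)) - 0.5) / dim  # center vectors
    C = np.zeros((len(vocab), dim))  # context vectors

    pairs: list[tuple[int, int]] = []
    for walk in walks:
        ids = [index[t] for t in walk]
        for i, center in enumerate(ids):
            lo = max(0, i - config.window)
            hi = min(len(ids), i + config.window + 1)
            for j in range(lo, hi):
                if j != i and ids[j] != center:
                    pairs.append((center, ids[j]))
    if not pairs:
        raise ValueError("walks contain no skip-gram pairs (all walks length 1?)")

    lr = config.learning_rate
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        total = 0.0
        for idx in order:
            center, ctx = pairs[idx]
            negs = rng.choice(len(vocab), size=config.negative, p=neg_probs)
            w = W[center]
            # positive pair
            c = C[ctx]
            score = 1.0 / (1.0 + math.exp(-float(np.dot(w, c))))
            total -= math.log(max(score, 1e-12))
            grad_w = (score - 1.0) * c
            C[ctx] = c - lr * (score - 1.0) * w
            # negatives
            for neg in negs:
                if neg == ctx:
                    continue
                cn = C[neg]
                s = 1.0 / (1.0 + math.exp(-float(np.dot(w, cn))))
                total -= math.log(max(1.0 - s, 1e-12))
                grad_w = grad_w + s * cn
                C[neg] = cn - lr * s * w
            W[center] = w - lr * grad_w
        losses.append(total / len(pairs))

    vectors = {tok: W[index[tok]] for tok in vocab if tok not in relation_names}
    rel_vectors = {tok: W[index[tok]] for tok in vocab if tok in relation_names}
    return EmbeddingSpace(
        dim=dim,
        method="walk",
        vectors=vectors,
        relation_vectors=rel_vectors,
        seed=config.seed,
        config=asdict(config),
        losses=losses,
    )


# ---------------------------------------------------------------------------
# knowledge-graph embeddings
# ---------------------------------------------------------------------------


def transe_score(space: EmbeddingSpace, s: str, r: str, o: str) -> float:
    """TransE triple plausibility: ``-‖v_s + v_r - v_o‖₂`` (0 is maximal)."""
    vs = space.vector(s)
    vr = space.relation_vector(r)
    vo = space.vector(o)
    return -float(np.linalg.norm(vs + vr - vo))


def rotate_score(space: EmbeddingSpace, s: str, r: str, o: str) -> float:
    """RotatE triple plausibility: ``-‖v_s ∘ v_r - v_o‖`` in ℂ^(d/2).

    The relation vector must have unit-modulus elements (validated to
    1e-6); rotation therefore preserves every entity norm.
    """
    cs = _as_complex(space.vector(s))
    cr = _as_complex(space.relation_vector(r))
    if np.any(np.abs(np.abs(cr) - 1.0) > _ROTATE_TOL):
        raise ValueError(f"relation {r!r} phases are not unit modulus")
    co = _as_complex(space.vector(o))
    return -float(np.linalg.norm(cs * cr - co))


def train_kge(
    graph: KnowledgeGraph, method: str, config: TrainingConfig
) -> EmbeddingSpace:
    """Train TransE or RotatE by margin-ranking SGD with uniform corruption.

    Each positive triple is paired with one corruption (head or tail
    replaced by a uniform random entity, probability 1/2 each); the
    subgradient of ``max(0, margin + d(pos) - d(neg))`` is applied. TransE
    entity vectors are re-normalized to unit L2 after each update; RotatE
    relations are parametrized by phase angles so their elements stay on
    the unit circle exactly.
    """
    if method not in ("transe", "rotate"):
        raise ValueError(f"unknown KGE method {method!r}; expected 'transe' or 'rotate'")
    entities = sorted(graph.concepts)
    if len(entities) < 2:
        raise ValueError("KGE training needs at least 2 entities")
    triples = graph.triples
    if not triples:
        raise ValueError("KGE training needs at least 1 triple")
    relations = sorted({t.relation for t in triples})
    e_index = {e: i for i, e in enumerate(entities)}
    r_index = {r: i for i, r in enumerate(relations)}
    trip_idx = np.array(
        [(e_index[t.subject], r_index[t.relation], e_index[t.object]) for t in triples]
    )
    rng = np.random.default_rng(config.seed)
    dim = config.dim
    lr = config.learning_rate
    losses: list[float] = []

    if method == "transe":
        bound = 6.0 / math.sqrt(dim)
        E = rng.uniform(-bound, bound, (len(entities), dim))
        R = rng.uniform(-bound, bound, (len(relations), dim))
        R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-12)
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        for _ in range(config.epochs):
            order = rng.permutation(len(triples))
            total = 0.0
            for ti in order:
                h, r, t = trip_idx[ti]
                h2, t2 = h, t
                if rng.random() < 0.5:
                    h2 = int(rng.integers(len(entities)))
                else:
                    t2 = int(rng.integers(len(entities)))
                u_p = E[h] + R[r] - E[t]
                u_n = E[h2] + R[r] - E[t2]
                d_p = float(np.linalg.norm(u_p))
                d_n = float(np.linalg.norm(u_n))
                loss = config.margin + d_p - d_n
                if loss <= 0:
                    continue
                total += loss
                g_p = u_p / max(d_p, 1e-12)
                g_n = u_n / max(d_n, 1e-12)
                E[h] -= lr * g_p
                E[t] += lr * g_p
                R[r] -= lr * (g_p - g_n)
                E[h2] += lr * g_n
                E[t2] -= lr * g_n
                for e in {h, t, h2, t2}:
                    E[e] /= max(float(np.linalg.norm(E[e])), 1e-12)
            losses.append(total / len(triples))
        vectors = {e: E[i].copy() for e, i in e_index.items()}
        rel_vectors = {r: R[i].copy() for r, i in r_index.items()}
    else:  # rotate
        if dim % 2:
            raise ValueError("rotate requires an even dimension")
        half = dim // 2
        scale = 0.5 / math.sqrt(half)
        Ec = (
            rng.uniform(-scale, scale, (len(entities), half))
            + 1j * rng.uniform(-scale, scale, (len(entities), half))
        )
        theta = rng.uniform(0.0, 2.0 * math.pi, (len(relations), half))
        for _ in range(config.epochs):
            order = rng.permutation(len(triples))
            total = 0.0
            for ti in order:
                h, r, t = trip_idx[ti]
                h2, t2 = h, t
                if rng.random() < 0.5:
                    h2 = int(rng.integers(len(entities)))
                else:
                    t2 = int(rng.integers(len(entities)))
                rot = np.exp(1j * theta[r])
                u_p = Ec[h] * rot - Ec[t]
                u_n = Ec[h2] * rot - Ec[t2]
                d_p = float(np.linalg.norm(u_p))
                d_n = float(np.linalg.norm(u_n))
                loss = config.margin + d_p - d_n
                if loss <= 0:
                    continue
                total += loss
                # d = ‖u‖ with u = s∘e^{iθ} − o:
                #   ∂d/∂s̄ = r̄∘u / (2d) per Wirtinger; real-parameter step uses conj(r)∘u/d
                #   ∂d/∂θ = −Im(ū ∘ s ∘ r)/d
                gs_p = np.conj(rot) * u_p / max(d_p, 1e-12)
                gs_n = np.conj(rot) * u_n / max(d_n, 1e-12)
                gth_p = -np.imag(np.conj(u_p) * Ec[h] * rot) / max(d_p, 1e-12)
                gth_n = -np.imag(np.conj(u_n) * Ec[h2] * rot) / max(d_n, 1e-12)
                Ec[h] -= lr * gs_p
                Ec[t] += lr * u_p / max(d_p, 1e-12)
                theta[r] -= lr * (gth_p - gth_n)
                Ec[h2] += lr * gs_n
                Ec[t2] -= lr * u_n / max(d_n, 1e-12)
            losses.append(total / len(triples))
        vectors = {e: _from_complex(Ec[i]) for e, i in e_index.items()}
        rel_vectors = {r: _from_complex(np.exp(1j * theta[i])) for r, i in r_index.items()}

    return EmbeddingSpace(
        dim=dim,
        method=method,
        vectors=vectors,
        relation_vectors=rel_vectors,
        seed=config.seed,
        config=asdict(config),
        losses=losses,
    )


def link_prediction_hits(
    space: EmbeddingSpace,
    graph: KnowledgeGraph,
    k: int = 3,
    filtered: bool = True,
) -> float:
    """Filtered hits@k for tail prediction over every triple in the graph.

    For each (s, r, o) the true tail is ranked among all entities by
    triple score; other known-true tails are excluded from the candidate
    list when ``filtered``. Ties rank pessimistically.
    """
    score = transe_score if space.method == "transe" else rotate_score
    entities = sorted(graph.concepts)
    known: dict[tuple[str, str], set[str]] = {}
    for t in graph.triples:
        known.setdefault((t.subject, t.relation), set()).add(t.object)
    hits = 0
    total = 0
    for t in graph.triples:
        true_score = score(space, t.subject, t.relation, t.object)
        others = known[(t.subject, t.relation)] - {t.object} if filtered else set()
        rank = 1
        for cand in entities:
            if cand == t.object or cand in others:
                continue
            if score(space, t.subject, t.relation, cand) >= true_score:
                rank += 1
        total += 1
        if rank <= k:
            hits += 1
    return hits / total if total else float("nan")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_space(space: EmbeddingSpace, path: str | Path) -> None:
    """Write entity vectors as TSV (code + d floats) with a JSON sidecar.

    The sidecar (``<path>.json``) carries method, dim, seed, the training
    config and the relation vectors.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for code in sorted(space.vectors):
            vec = "\t".join(repr(float(x)) for x in space.vectors[code])
            fh.write(f"{code}\t{vec}\n")
    sidecar = {
        "method": space.method,
        "dim": space.dim,
        "seed": space.seed,
        "config": space.config,
        "losses": space.losses,
        "relation_vectors": {
            name: [float(x) for x in vec]
            for name, vec in sorted(space.relation_vectors.items())
        },
    }
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def load_space(path: str | Path) -> EmbeddingSpace:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            vectors[fields[0]] = np.array([float(x) for x in fields[1:]])
    return EmbeddingSpace(
        dim=sidecar["dim"],
        method=sidecar["method"],
        vectors=vectors,
        relation_vectors={
            name: np.array(vec) for name, vec in sidecar["relation_vectors"].items()
        },
        seed=sidecar["seed"],
        config=sidecar.get("config", {}),
        losses=sidecar.get("losses", []),
    )
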