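# Methods

## The pipeline model

`scai` treats clinical knowledge as a set of semantic triples
subject–relation–object over coded concepts and asks one question: does
prepending question-specific verbalized triples to a prompt improve a
question-answering backend on multiple-choice items, relative to the
bare prompt? The pipeline is deliberately single-hop: a question's stem
is tagged to concept codes, the codes are widened by embedding
similarity, and only triples *incident* to the widened code set are
considered. No multi-hop traversal, reasoning, or re-ranking is
attempted; the working assumption is that a clinically useful fact for a
question mentions at least one concept the question itself mentions (or
one of its nearest embedding neighbors).

The relation registry partitions the 40 relation types into 13
context-eligible ("rag_use") clinical relations — causes, clinical
course of, definitional manifestation of, diagnoses, finding method of,
has adverse reaction, has contraindication, has indication, occurs in,
pathological process of, predisposes, prevents, treats — and 27
structural/ontological relations (isa, part of, finding site of, …)
whose triples are filtered out of contexts. The registry also records
corpus-scale frequency hints per relation; the per-row figures are kept
verbatim even though their subtotals are not mutually consistent, and
they are used only as a default sampling mix for synthetic graphs (the
mix is normalized over the 40 row values, so each relation's share is
its row value divided by the row sum).

## Embeddings

Two families are trained from the same graph and combined at retrieval
time by union of neighbor sets (the combination rule for the ensemble is
an open design point; union is the simplest rule that cannot hide a
retrieved fact).

**Walk-based graph embeddings.** The graph is deconstructed into
code–relation incidence pairs (each triple contributes subject–relation
and object–relation edges); optional sentence co-occurrence pairs can be
added. Over this undirected pair graph we run second-order biased random
walks with return parameter `p` and in-out parameter `q` (unnormalized
next-step weights 1/p back to the previous node, 1 to a common neighbor,
1/q outward); `p = q = 1` reduces exactly to uniform DeepWalk sampling,
which a chi-square test on next-step frequencies verifies. Walks are
embedded by skip-gram with negative sampling (unigram^0.75 noise
distribution, plain SGD at a fixed learning rate, per-epoch mean NLL
recorded and required to decrease). Relation tokens are trained like any
node but stored apart from entities so cosine search never returns a
relation as a "similar concept". The configurable-bias walk is our
generalization of the family of walk methods; it does not claim to
reproduce any unpublished variant.

**Knowledge-graph embeddings.** TransE scores a triple as
`-‖v_s + v_r − v_o‖₂`; RotatE as `-‖v_s ∘ v_r − v_o‖` with entities in
ℂ^(d/2) (stored as interleaved re/im reals) and relations as unit-modulus
phase vectors. Both train with margin ranking loss against uniform
corruptions (head or tail replaced with probability ½). TransE entity
vectors are re-normalized to unit L2 after each update (the classic
regularizer); RotatE relations are parametrized directly by phase
angles, so unit modulus holds exactly at every step rather than being
restored by projection. Negative sampling is uniform, not
self-adversarial — the simplest published variant, sufficient for the
planted-recovery scales exercised here.

## Retrieval and prompting

Defaults: `k = 5` neighbors per seed per space, context cap 40
sentences, both configurable. The cap exists because generation backends
have input-size limits; truncation keeps triples incident to the
original question codes ahead of neighbor-only triples, since
question-specific knowledge is the point of retrieval. Verbalization is
templated — `"<subject label>" (<tag>) <relation> "<object label>"
(<tag>)`, tag parenthetical omitted when empty — and the prompt template
is versioned (`v1`), with the native and RAG prompts differing only by
the leading context block. Contexts are deduplicated and byte-stable:
adjacency queries order triples by (relation, counterpart code), so the
same inputs always produce the same context file.

## Answer backends and parsing

A backend is any callable from prompt string to response string. The
shipped rule-based mock is keyed by planted facts: if the question's key
sentence appears in the prompt it answers the keyed letter; otherwise it
guesses a uniformly random letter with probability `c` (its
confabulation propensity) or stays silent. Guessing uniformly over all
letters puts unaided accuracy at chance (1/number of choices), which is
the useful null for the paired test; a `guess_includes_key=False` switch
makes the unaided mock always wrong instead, for worst-case scenarios.
The mock derives its randomness from (seed, question id), so it is a
pure function of the prompt at a fixed seed.

Free-text responses are reduced to a letter by precedence-ordered cues:
an explicit "answer …" statement, then a parenthesized letter, then a
bare "X)" marker, then "option X", then a bare-letter response. A
response asserting no valid letter parses to null — silence, which is
scored as incorrect but never as confabulation. These precedence rules
are an artifact-level choice; ambiguous generative output ultimately
needs human adjudication, which a library cannot provide.

## Evaluation statistics

Questions vary in difficulty, so conditions are compared with Cochran's
Q over question blocks:
`Q = (k−1)[k ΣG_j² − (ΣG_j)²] / (k ΣL_i − ΣL_i²)` with column totals
`G_j` and block totals `L_i`. At k = 2 this reduces to McNemar's
`(b − c)²/(b + c)` over the discordant blocks, which the suite verifies
on random tables. All-concordant tables get Q = 0 and p = 1 by
convention.

The "exact" p-value is the conditional within-block permutation test:
permute each block's outcomes across conditions and count assignments
with Q at least the observed value (observed included). At k = 2 only
discordant blocks vary, each flipping with probability ½, so the
distribution collapses to binomial tail sums computed with exact integer
arithmetic regardless of the total block count; this equals the
two-sided exact binomial McNemar p with the doubling convention
(min(1, 2·min-tail)) whenever b ≠ c. For k > 2 the test enumerates all
distinct within-block assignments when their product is ≤ 2·10⁵ and
otherwise falls back to seeded Monte-Carlo (default 10⁵ draws, p
estimated with the +1 correction that keeps the observed assignment in
the reference set).

Confabulation is counted as wrong *nonnull* answers; the rate is
count/n × 100 reported to one decimal, rounded half-up to match
conventional table typography. Silent answers count as incorrect in the
outcome table — correctness, not assertiveness, is what the Q test
compares — and the report enforces correct + confabulation + silent = n.

## The synthetic world

`scai.synthetic` emulates the shape, not the content, of a clinical
corpus: concepts get unique pronounceable pseudo-labels and semantic
tags; triples are sampled to the registry's relation mix over a
spanning-tree-connected core; the lexicon covers every label; and each
exam question plants one context-eligible triple whose subject label
appears in the stem, whose object label is the correct choice, and whose
distractors are labels of concepts unconnected to the subject. Defaults
— 300 concepts, 900 triples (mean degree 6), 100 questions of 5 choices
— give a desk-scale corpus on which the paired comparison has ample
power.

What passing the closed loop does and does not show: it demonstrates
that tagging, expansion, retrieval, filtering, verbalization, prompting,
parsing and scoring compose correctly and deterministically — if the
planted fact survives the pipeline, the keyed mock proves it arrived. It
does *not* show that real clinical text tags cleanly (invented labels
are unambiguous by construction), that real knowledge graphs contain the
needed fact within one hop, or that a real generative model uses a
correct context correctly. Those are properties of data and models, not
of this pipeline.

The curation rule engine is exercised against three fixed exclusion
profiles of text-only licensing-exam sample sets (e.g. 119 questions, 29
visual and 3 nonvisual exclusions, 87 usable), with exclusion
annotations scattered at seeded-random positions.

## Problem sizes and numerical choices

The test suite and the acceptance script run at small, fixed scales
chosen as the smallest sizes at which each property is decisively
testable: clique-separation for skip-gram on two 5-cliques (d = 128 and
512), link-prediction recovery on a planted 30-entity graph (hits@3
against a 3/29 chance rate), brute-force neighbor agreement on 200 codes
at d = 128, DeepWalk equivalence on >10⁴ sampled steps, and the closed
loop on the default 100-question world with a d = 32 walk space.
RotatE's unit-modulus tolerance is 1e-6; cosine similarity raises on
zero vectors rather than returning a conventional value; duplicate
triples collapse silently on load; unknown relations are stored but
never context-eligible (fail-open storage, fail-closed retrieval).
Embedding training uses one thread, plain SGD, and a fixed seed
throughout, making every trained space bit-reproducible.

## Known limitations

- The tagger is exact-match after normalization; no inflection,
  abbreviation expansion, or spelling tolerance.
- Retrieval is single-hop; facts two edges from every mentioned concept
  are unreachable by design.
- The ensemble rule (union of neighbor sets) and the truncation priority
  are design choices among several defensible ones; both are isolated
  behind configuration.
- The HTTP backend adapter is shipped untested: exercising it requires
  an external generation endpoint, which the test suite deliberately
  avoids.
- Printed p-values in published comparisons of this design are not
  always recoverable from marginals (some Q values admit no integer
  discordant split); the acceptance computations therefore restrict to
  the cases with exact integer solutions.
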