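# scai — semantic clinical AI: knowledge-graph RAG for medical multiple-choice QA

`scai` implements a retrieval-augmented generation (RAG) pipeline that
injects formally represented clinical knowledge — semantic triples of the
form *subject–relation–object* over coded concepts, e.g.
`penicillin —treats→ pneumococcal pneumonia` — into the prompt of a
question-answering backend, together with the paired statistical
evaluation used to decide whether the augmentation helps.

It is aimed at clinical-informatics researchers who want to study the
mechanics of semantic augmentation (retrieval, relation filtering,
verbalization, paired testing) without licensed terminologies, copyrighted
exam content, or any large language model: the package ships a synthetic
world generator with planted facts and a deterministic rule-based mock
backend, so the whole loop is testable on a laptop.

## What it does

1. **Knowledge graph** (`scai.kg`): a triple store over coded concepts
   with a 40-type relation registry; 13 relation types (causes, treats,
   diagnoses, has adverse reaction, …) are flagged as eligible for
   context generation, while structural relations (isa, part of, …) are
   filtered out to keep contexts small and clinically informative.
2. **Concept tagging** (`scai.tagger`): a deterministic lexicon tagger
   (greedy longest match over normalized tokens) that maps question stems
   to concept codes.
3. **Embeddings** (`scai.embeddings`): an ensemble of
   - biased second-order random walks (node2vec-style `p`/`q`; `p=q=1`
     is DeepWalk) over the deconstructed-triple pair graph, embedded by
     skip-gram with negative sampling, and
   - knowledge-graph embeddings scoring whole triples: **TransE**
     (relation as translation, score `-‖v_s + v_r − v_o‖₂`) and
     **RotatE** (relation as unit-modulus complex rotation, score
     `-‖v_s ∘ v_r − v_o‖`),
   with cosine-similarity search
   `S_cos(x, y) = ⟨x, y⟩ / (‖x‖·‖y‖)` for neighbor expansion.
4. **Retrieval** (`scai.retrieval`): expand question codes with top-k
   cosine neighbors, pull incident triples, filter by relation
   eligibility, and verbalize, e.g.
   `"urinalysis" (procedure) diagnoses "crystalluria" (finding)`.
5. **Answering** (`scai.backend`, `scai.pipeline`): a pluggable
   prompt→text backend contract with a rule-based mock (answers correctly
   iff the planted fact is in its prompt; otherwise guesses with
   propensity `c` or stays silent) and robust answer-letter parsing.
6. **Evaluation** (`scai.evaluation`): per-condition accuracy, the
   **confabulation rate** (wrong *nonnull* answers — asserting an answer
   rather than staying silent), and the **exact Cochran Q test with
   question blocks** (at k = 2 conditions, McNemar's
   `Q = (b − c)² / (b + c)` over discordant questions, with the exact
   conditional permutation p-value).

## Worked example

```sh
scai simulate --out world --seed 7 --n-concepts 60 --n-triples 180 --n-questions 12
scai embed    --graph world/triples.tsv --out spaces --methods walk,transe \
              --dim 64 --epochs 3 --walk-length 8 --walks-per-node 3 --seed 7
scai answer   --graph world/triples.tsv --lexicon world/lexicon.tsv \
              --exam world/exam.json --condition native --out runs/native.jsonl --seed 7
scai answer   --graph world/triples.tsv --lexicon world/lexicon.tsv \
              --exam world/exam.json --spaces spaces --condition rag \
              --cap 1000 --out runs/rag.jsonl --seed 7
scai evaluate --native runs/native.jsonl --rag runs/rag.jsonl \
              --exam world/exam.json --out report
```

prints

```
condition      correct, n (%)   confabulation, n (%)  silent
native              2 (16.7%)             10 (83.3%)       0
rag               12 (100.0%)               0 (0.0%)       0
Cochran Q = 10.00, exact p = 0.002 (enumeration)
```

Reading: unaided, the mock backend guesses (2/12 correct is chance for
5-choice questions, and all 10 misses are confabulations — asserted wrong
answers). With retrieval-augmented prompts every planted fact reaches the
backend and all 12 questions are answered correctly. The paired exact
Cochran Q test over question blocks (10 discordant questions, all
favoring RAG) rejects the null of no condition effect at p = 0.002.
Per-question context files are archived under `runs/contexts_rag/`, one
verbalized sentence per line.

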