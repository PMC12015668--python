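"""One-call orchestration of the answer workflow for a whole exam.

Thin glue over the tagger, retrieval, and backend modules: tag each stem
to concept codes, build the clinical context (RAG condition only), render
the prompt, and collect one answer record per question.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .backend import AnswerRecord, Backend, ask
from .embeddings import EmbeddingSpace
from .exam import Question
from .kg import KnowledgeGraph
from .retrieval import RagContext, RetrievalConfig, build_context, build_prompt
from .tagger import Lexicon, extract_codes

__all__ = ["answer_exam"]


def answer_exam(
    graph: KnowledgeGraph,
    lexicon: Lexicon,
    questions: Sequence[Question],
    backend: Backend,
    condition: str,
    spaces: Iterable[EmbeddingSpace] = (),
    config: Optional[RetrievalConfig] = None,
) -> tuple[list[AnswerRecord], dict[str, RagContext]]:
    """Answer every question under one condition; order preserved.

    Returns (records, contexts); contexts is empty for the native
    condition, which skips tagging and retrieval entirely.
    """
    if condition not in ("native", "rag"):
        raise ValueError(f"condition must be 'native' or 'rag', got {condition!r}")
    config = config or RetrievalConfig()
    spaces = list(spaces)
    records: list[AnswerRecord] = []
    contexts: dict[str, RagContext] = {}
    for q in questions:
        context = None
        if condition == "rag":
            codes = extract_codes(q.stem, lexicon)
            context = build_context(graph, spaces, codes, config)
            contexts[q.id] = context
        bundle = build_prompt(q, context, config.template_id)
        records.append(ask(backend, bundle, condition))
    return records, contexts
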