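"""Pluggable answer backends and answer-letter parsing.

The pipeline only requires a backend to be a callable mapping a prompt
string to a response string. Shipped implementations:

* :class:`RuleBasedMock` — a deterministic test double. For a registered
  question it answers the keyed letter whenever the prompt contains the
  question's key sentence (the planted fact); otherwise it guesses a
  uniformly random letter with probability ``c`` (its confabulation
  propensity) or stays silent. Randomness is derived from (seed, question
  id) so the mock is a pure function of the prompt at a fixed seed.
* :class:`HTTPBackend` — a thin JSON-over-HTTP adapter for an external
  text-generation endpoint, behind the same contract (not exercised by
  the test suite; no model is required to run the pipeline).

Free-text responses are reduced to a choice letter by
:func:`parse_answer`; an unparseable response is recorded as silence
(``None``), never as an error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .exam import Question
from .retrieval import PromptBundle

logger = logging.getLogger(__name__)

__all__ = [
    "AnswerRecord",
    "parse_answer",
    "ask",
    "ask_all",
    "RuleBasedMock",
    "HTTPBackend",
    "save_records",
    "load_records",
]

Backend = Callable[[str], str]

# Assertion cues in precedence order: an explicit "answer ..." statement
# beats a parenthesized letter, which beats "option X", which beats a
# bare-letter response.
_CUES = (
    re.compile(r"\banswer(?:\s+is)?\s*[:\-]?\s*\(?([A-Z])\)?(?![A-Za-z])", re.IGNORECASE),
    re.compile(r"\(([A-Z])\)"),
    re.compile(r"\b([A-Z])\)"),
    re.compile(r"\boption\s+\(?([A-Z])\)?(?![A-Za-z])", re.IGNORECASE),
    re.compile(r"^\s*([A-Z])\s*[.!]?\s*$"),
)


def parse_answer(response: str, letters: Iterable[str]) -> Optional[str]:
    """Extract the first asserted choice letter from a free-text response.

    Cues are tried in precedence order; within a cue the first match whose
    letter is a valid choice wins. Returns ``None`` when nothing valid is
    asserted — silence by definition, not an error.
    """
    valid = {letter.upper() for letter in letters}
    if not valid:
        raise ValueError("letters must be nonempty")
    for cue in _CUES:
        for m in cue.finditer(response):
            letter = m.group(1).upper()
            if letter in valid:
                return letter
    return None


@dataclass
class AnswerRecord:
    """One backend response to one question under one condition."""

    question_id: str
    condition: str  # "native" | "rag"
    raw_response: str
    letter: Optional[str] = None
    correct: Optional[bool] = None  # set only after scoring against the key
    error: str = ""

    @property
    def silent(self) -> bool:
        return self.letter is None


def ask(backend: Backend, bundle: PromptBundle, condition: str = "native") -> AnswerRecord:
    """Present one prompt; never raises on backend failure or junk output.

    A backend exception is recorded as silence with an error note.
    """
    letters = sorted(bundle.choices)
    try:
        raw = backend(bundle.prompt)
    except Exception as exc:  # noqa: BLE001 - failure is data here
        logger.warning("backend failed on question %s: %s", bundle.question_id, exc)
        return AnswerRecord(bundle.question_id, condition, "", None, error=str(exc))
    return AnswerRecord(
        bundle.question_id, condition, raw, parse_answer(raw, letters)
    )


def ask_all(
    backend: Backend, bundles: Sequence[PromptBundle], condition: str = "native"
) -> list[AnswerRecord]:
    """One record per bundle, order preserved."""
    return [ask(backend, bundle, condition) for bundle in bundles]


@dataclass
class _MockEntry:
    stem: str
    key_sentence: str
    key_letter: str
    letters: tuple[str, ...]


class RuleBasedMock:
    """Deterministic knowledge-keyed answer backend.

    ``c`` is the confabulation propensity: with the key sentence absent
    from the prompt, the mock guesses a letter with probability ``c``
    (uniform over all choice letters, so unaided accuracy sits at chance
    level) and stays silent otherwise. ``guess_includes_key=False``
    restricts guesses to non-key letters (accuracy zero when unaided).
    Unregistered questions always get silence.
    """

    SILENCE = "I cannot determine the answer."

    def __init__(self, c: float = 1.0, seed: int = 0, guess_includes_key: bool = True):
        if not 0.0 <= c <= 1.0:
            raise ValueError("confabulation propensity c must be in [0, 1]")
        self.c = c
        self.seed = seed
        self.guess_includes_key = guess_includes_key
        self._entries: dict[str, _MockEntry] = {}

    def register(
        self, question_id: str, stem: str, key_sentence: str, key_letter: str,
        letters: Iterable[str],
    ) -> None:
        self._entries[question_id] = _MockEntry(
            stem, key_sentence, key_letter, tuple(sorted(letters))
        )

    @classmethod
    def from_exam(
        cls, questions: Iterable[Question], c: float = 1.0, seed: int = 0,
        guess_includes_key: bool = True,
    ) -> "RuleBasedMock":
        mock = cls(c=c, seed=seed, guess_includes_key=guess_includes_key)
        for q in questions:
            mock.register(q.id, q.stem, q.key_sentence, q.key, q.letters)
        return mock

    def _rng(self, question_id: str) -> random.Random:
        digest = hashlib.sha256(f"{self.seed}:{question_id}".encode()).digest()
        return random.Random(int.from_bytes(digest[:8], "big"))

    def __call__(self, prompt: str) -> str:
        entry = None
        for qid in sorted(self._entries):
            if self._entries[qid].stem and self._entries[qid].stem in prompt:
                entry, question_id = self._entries[qid], qid
                break
        if entry is None:
            return self.SILENCE
        if entry.key_sentence and entry.key_sentence in prompt:
            return f"Answer: {entry.key_letter}"
        rng = self._rng(question_id)
        if rng.random() < self.c:
            pool = (
                entry.letters
                if self.guess_includes_key
                else tuple(l for l in entry.letters if l != entry.key_letter)
            )
            return f"Answer: {rng.choice(pool)}"
        return self.SILENCE


class HTTPBackend:
    """JSON-over-HTTP adapter: POST {"prompt": ...} -> {"text": ...}.

    Retries transient failures up to ``retries`` times; a final failure
    propagates to :func:`ask`, which records it as silence with a note.
    """

    def __init__(self, url: str, timeout: float = 60.0, retries: int = 2):
        self.url = url
        self.timeout = timeout
        self.retries = retries

    def __call__(self, prompt: str) -> str:
        import urllib.request

        payload = json.dumps({"prompt": prompt}).encode("utf-8")
        last_exc: Exception = RuntimeError("unreachable")
        for _ in range(self.retries + 1):
            try:
                req = urllib.request.Request(
                    self.url, data=payload, headers={"Content-Type": "application/json"}
                )
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    return json.loads(resp.read().decode("utf-8"))["text"]
            except Exception as exc:  # noqa: BLE001
                last_exc = exc
        raise last_exc


def save_records(records: Sequence[AnswerRecord], path: str | Path) -> None:
    """Answer records as JSON-lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "question_id": r.question_id,
                        "condition": r.condition,
                        "raw_response": r.raw_response,
                        "letter": r.letter,
                        "correct": r.correct,
                        "error": r.error,
                    }
                )
                + "\n"
            )


def load_records(path: str | Path) -> list[AnswerRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            records.append(
                AnswerRecord(
                    d["question_id"], d["condition"], d["raw_response"],
                    d.get("letter"), d.get("correct"), d.get("error", ""),
                )
            )
    return records
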