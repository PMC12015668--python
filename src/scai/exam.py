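"""Multiple-choice exam ingest and curation.

Exams are JSON files of lettered multiple-choice questions with an answer
key. Ingest applies a curation rule engine mirroring how text-only
question sets are prepared for language-model evaluation: any question
annotated with an exclusion (a visual component such as a photograph or
radiograph, or a nonvisual reason such as a multipart answer that does not
survive conversion to a text file) is dropped, and the counts are
reported per category and reason.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

__all__ = ["Question", "Exclusion", "CurationReport", "load_exam", "save_exam", "curate"]

_LETTER = re.compile(r"^[A-Z]$")

EXCLUSION_CATEGORIES = ("visual", "nonvisual")


@dataclass(frozen=True)
class Exclusion:
    """Why a question cannot be presented as plain text."""

    category: str  # "visual" | "nonvisual"
    reason: str

    def __post_init__(self) -> None:
        if self.category not in EXCLUSION_CATEGORIES:
            raise ValueError(
                f"exclusion category must be one of {EXCLUSION_CATEGORIES}, "
                f"got {self.category!r}"
            )


@dataclass
class Question:
    """One lettered multiple-choice question with its keyed answer."""

    id: str
    stem: str
    choices: dict[str, str]
    key: str
    exclusion: Optional[Exclusion] = None
    key_sentence: str = ""  # the planted fact entailing the key (synthetic exams)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("question id must be nonempty")
        if len(self.choices) < 2:
            raise ValueError(f"question {self.id!r} needs at least 2 choices")
        for letter in self.choices:
            if not _LETTER.match(letter):
                raise ValueError(
                    f"question {self.id!r}: choice letter {letter!r} must be A-Z"
                )
        if self.key not in self.choices:
            raise ValueError(
                f"question {self.id!r}: key {self.key!r} not among choices "
                f"{sorted(self.choices)}"
            )

    @property
    def letters(self) -> list[str]:
        return sorted(self.choices)


@dataclass
class CurationReport:
    """Exclusion accounting for one exam manifest."""

    total: int
    kept: int
    excluded_by_category: dict[str, int] = field(default_factory=dict)
    excluded_by_reason: dict[str, int] = field(default_factory=dict)

    @property
    def excluded(self) -> int:
        return self.total - self.kept


def curate(questions: Sequence[Question]) -> tuple[list[Question], CurationReport]:
    """Drop questions carrying an exclusion annotation; account for them."""
    kept: list[Question] = []
    by_cat: Counter[str] = Counter()
    by_reason: Counter[str] = Counter()
    for q in questions:
        if q.exclusion is None:
            kept.append(q)
        else:
            by_cat[q.exclusion.category] += 1
            by_reason[q.exclusion.reason] += 1
    return kept, CurationReport(
        total=len(questions),
        kept=len(kept),
        excluded_by_category=dict(by_cat),
        excluded_by_reason=dict(by_reason),
    )


def load_exam(path: str | Path) -> list[Question]:
    """Read an exam JSON file.

    Schema: ``{"questions": [{"id", "stem", "choices": {letter: text},
    "key", "exclusion"?: {"category", "reason"}, "key_sentence"?}]}``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    questions = []
    for item in raw["questions"]:
        excl = item.get("exclusion")
        questions.append(
            Question(
                id=str(item["id"]),
                stem=item["stem"],
                choices=dict(item["choices"]),
                key=item["key"],
                exclusion=Exclusion(excl["category"], excl["reason"]) if excl else None,
                key_sentence=item.get("key_sentence", ""),
            )
        )
    ids = [q.id for q in questions]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate question ids")
    return questions


def save_exam(questions: Sequence[Question], path: str | Path) -> None:
    items = []
    for q in questions:
        item: dict = {"id": q.id, "stem": q.stem, "choices": q.choices, "key": q.key}
        if q.exclusion is not None:
            item["exclusion"] = {
                "category": q.exclusion.category,
                "reason": q.exclusion.reason,
            }
        if q.key_sentence:
            item["key_sentence"] = q.key_sentence
        items.append(item)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"questions": items}, fh, indent=1)
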