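"""Deterministic lexicon-based concept tagger.

Maps free text (question stems, reference sentences) to concept codes by
greedy left-to-right longest match over normalized tokens. This is a
deliberately reduced, fully deterministic stand-in for a clinical NLP
parser: the downstream pipeline only needs the set of concept codes
mentioned by a question, not syntax or negation.

Matching is token-bounded: a lexicon term never matches inside a word
(so "men" does not fire inside "abdomen"). Offsets are 0-based half-open
character positions into the *original* text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["Lexicon", "TagSpan", "normalize", "tag_text", "extract_codes", "load_lexicon"]

_PUNCT = re.compile(r"[^\w\s]|_")
_WS = re.compile(r"\s+")
_TOKEN = re.compile(r"\w+")


def normalize(text: str) -> str:
    """Lower-case, strip punctuation to spaces, collapse whitespace.

    Idempotent: ``normalize(normalize(t)) == normalize(t)``.
    """
    text = _PUNCT.sub(" ", text.lower())
    return _WS.sub(" ", text).strip()


@dataclass(frozen=True)
class TagSpan:
    """A tagged region of text: half-open character offsets plus the code."""

    start: int
    end: int
    code: str
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("span must satisfy 0 <= start < end")


class Lexicon:
    """Surface term -> concept code map (many terms may share one code).

    Terms are stored normalized. A term mapping to two different codes is an
    ambiguity the pipeline cannot resolve, so construction fails fast.
    """

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]] = ()) -> None:
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._entries: dict[str, str] = {}
        self._max_tokens = 0
        for term, code in items:
            self.add(term, code)

    def add(self, term: str, code: str) -> None:
        key = normalize(term)
        if not key:
            raise ValueError(f"lexicon term {term!r} is empty after normalization")
        if not code:
            raise ValueError(f"lexicon term {term!r} has empty code")
        if key in self._entries and self._entries[key] != code:
            raise ValueError(
                f"ambiguous lexicon: term {key!r} maps to both "
                f"{self._entries[key]!r} and {code!r}"
            )
        self._entries[key] = code
        self._max_tokens = max(self._max_tokens, len(key.split(" ")))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, term: str) -> bool:
        return normalize(term) in self._entries

    def code(self, term: str) -> str:
        return self._entries[normalize(term)]

    @property
    def max_tokens(self) -> int:
        return self._max_tokens

    def items(self) -> list[tuple[str, str]]:
        return sorted(self._entries.items())


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a two-column TSV (term, code) into a :class:`Lexicon`."""
    lex = Lexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected term<TAB>code")
            lex.add(fields[0], fields[1])
    return lex


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#term\tcode\n")
        for term, code in lexicon.items():
            fh.write(f"{term}\t{code}\n")


def tag_text(text: str, lexicon: Lexicon) -> list[TagSpan]:
    """Greedy left-to-right longest-match tagging.

    Each character belongs to at most one span; spans come back in text
    order. The match unit is the word token of the normalized text, so the
    reported character offsets cover whole words of the original text.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    tokens = [(m.group(0), m.start(), m.end()) for m in _TOKEN.finditer(text)]
    norm_tokens = [normalize(tok) for tok, _, _ in tokens]
    spans: list[TagSpan] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        # longest candidate first
        for width in range(min(lexicon.max_tokens, n - i), 0, -1):
            candidate = " ".join(t for t in norm_tokens[i : i + width] if t)
            if candidate and candidate in lexicon:
                start = tokens[i][1]
                end = tokens[i + width - 1][2]
                spans.append(
                    TagSpan(start, end, lexicon.code(candidate), text[start:end])
                )
                i += width
                matched = True
                break
        if not matched:
            i += 1
    return spans


def extract_codes(text: str, lexicon: Lexicon) -> list[str]:
    """Distinct concept codes in order of first occurrence in ``text``."""
    seen: dict[str, None] = {}
    for span in tag_text(text, lexicon):
        seen.setdefault(span.code, None)
    return list(seen)
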