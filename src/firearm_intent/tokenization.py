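"""Shared tokenizer and sentence segmentation.

Every module that touches text (lexicon matching, candidate-term scoring,
context-modifier detection, the pattern dependency parser) goes through the
same tokenizer, so matching semantics are identical everywhere: case-folded,
whitespace-split, with punctuation emitted as separate single-character
tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# Word tokens keep internal apostrophes ("pt's"); everything else that is
# not whitespace becomes a one-character punctuation token.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z0-9]+)?|[^\sA-Za-z0-9]")

# Abbreviations after which a period does not end a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "st", "vs", "pt", "approx", "no", "e.g", "i.e"}
)


@dataclass(frozen=True)
class Token:
    """A token with its character span (0-based, half-open) in the source."""

    text: str
    start: int
    end: int


def tokenize(text: str) -> list[str]:
    """Case-folded token strings for *text*."""
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


def tokenize_with_spans(text: str) -> list[Token]:
    return [
        Token(m.group(0).lower(), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


_BOUNDARY_RE = re.compile(r"[.!?]+")


def split_sentences(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[tuple[int, int]]:
    """Character spans of sentences in *text*.

    A boundary is a run of ``.``, ``!`` or ``?`` followed by whitespace and
    an upper-case letter (or end of text), unless the word before a period
    is a guarded abbreviation. Newlines always terminate a sentence, which
    matches how clinical notes lay out one statement per line.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            if text[start:i].strip():
                spans.append((start, i))
            start = i + 1
            i += 1
            continue
        m = _BOUNDARY_RE.match(text, i)
        if m is None:
            i += 1
            continue
        end = m.end()
        # Abbreviation guard: the word immediately before a lone period.
        if m.group(0) == ".":
            wm = re.search(r"([A-Za-z.]+)$", text[start:i])
            if wm and wm.group(1).lower().rstrip(".") in abbreviations:
                i = end
                continue
        # Sentence ends if followed by whitespace + capital, or text ends.
        rest = text[end:]
        follow = re.match(r"\s+([A-Z0-9])", rest)
        if rest == "" or rest.isspace() or follow:
            if text[start:end].strip():
                spans.append((start, end))
            # skip following whitespace
            ws = re.match(r"\s*", rest)
            start = end + ws.end()
            i = start
        else:
            i = end
    if start < n and text[start:].strip():
        spans.append((start, n))
    return spans
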