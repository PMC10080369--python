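"""Intent lexicon: data model, TSV/CSV format, candidate scoring, matching.

A lexicon term is a 1-5 token surface form with a category (shooting verb,
explicit-intent cue, police actor, confusion term, ...) and optional
attribute tags (e.g. ``location=inside``). Confusion terms exist purely to
suppress spurious matches of shorter informative terms they contain — the
canonical example being "police report", which must not trigger the
police-actor category.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .tokenization import tokenize

logger = logging.getLogger(__name__)

MAX_TERM_TOKENS = 5

#: Closed category registry. Loaders reject rows outside this set; pass a
#: custom registry to extend it without touching code.
DEFAULT_CATEGORIES = (
    "shooting_verb",
    "firearm_term",
    "incident_location",
    "explicit_intent_accident",
    "explicit_intent_assault",
    "explicit_intent_self_harm",
    "explicit_intent_legal",
    "explicit_intent_unknown",
    "police_actor",
    "confusion_term",
    "no_info_attestation",
    # context-trigger categories share the file dialect
    "negation_trigger",
    "history_trigger",
    "other_subject_trigger",
    "scope_terminator",
)

CONFUSION_CATEGORY = "confusion_term"


class LexiconError(ValueError):
    """Malformed lexicon file or invalid term."""


@dataclass(frozen=True)
class LexiconTerm:
    """A surface form (stored as a case-folded token tuple) with category."""

    surface: tuple[str, ...]
    category: str
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.surface) <= MAX_TERM_TOKENS:
            raise LexiconError(
                f"term {' '.join(self.surface)!r} has {len(self.surface)} tokens; "
                f"must be 1-{MAX_TERM_TOKENS}"
            )
        object.__setattr__(self, "tags", dict(self.tags))

    def __hash__(self) -> int:  # tags excluded: (surface, category) is the key
        return hash((self.surface, self.category))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LexiconTerm):
            return NotImplemented
        return (self.surface, self.category) == (other.surface, other.category)

    @property
    def text(self) -> str:
        return " ".join(self.surface)

    @classmethod
    def from_text(
        cls, text: str, category: str, tags: Mapping[str, str] | None = None
    ) -> "LexiconTerm":
        return cls(tuple(tokenize(text)), category, tags or {})


class Lexicon:
    """A validated set of :class:`LexiconTerm` with fast n-gram lookup."""

    def __init__(
        self,
        terms: Iterable[LexiconTerm] = (),
        version: str = "0",
        categories: Sequence[str] = DEFAULT_CATEGORIES,
    ) -> None:
        self.version = version
        self.categories = tuple(categories)
        self._category_rank = {c: i for i, c in enumerate(self.categories)}
        self._terms: dict[tuple[tuple[str, ...], str], LexiconTerm] = {}
        for t in terms:
            self.add(t)

    def add(self, term: LexiconTerm) -> None:
        if term.category not in self._category_rank:
            raise LexiconError(f"unknown category {term.category!r}")
        key = (term.surface, term.category)
        if key in self._terms:
            logger.warning("duplicate lexicon row collapsed: %s", term.text)
        self._terms[key] = term

    @property
    def terms(self) -> list[LexiconTerm]:
        return list(self._terms.values())

    @property
    def confusion_terms(self) -> list[LexiconTerm]:
        return [t for t in self._terms.values() if t.category == CONFUSION_CATEGORY]

    def terms_of_category(self, category: str) -> list[LexiconTerm]:
        return [t for t in self._terms.values() if t.category == category]

    def surfaces_of_category(self, category: str) -> set[tuple[str, ...]]:
        return {t.surface for t in self.terms_of_category(category)}

    def category_rank(self, category: str) -> int:
        return self._category_rank[category]

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term: LexiconTerm) -> bool:
        return (term.surface, term.category) in self._terms

    def merged_with(self, other: "Lexicon") -> "Lexicon":
        cats = list(self.categories)
        cats += [c for c in other.categories if c not in cats]
        return Lexicon(self.terms + other.terms, self.version, cats)


def _parse_tags(raw: str, lineno: int) -> dict[str, str]:
    raw = raw.strip()
    if raw in {"", "-", "–"}:
        return {}
    tags: dict[str, str] = {}
    for piece in raw.split(";"):
        piece = piece.strip()
        if not piece:
            continue
        if "=" not in piece:
            raise LexiconError(f"line {lineno}: malformed tag {piece!r} (want key=value)")
        k, v = piece.split("=", 1)
        if not k.strip() or not v.strip():
            raise LexiconError(f"line {lineno}: malformed tag {piece!r}")
        tags[k.strip()] = v.strip()
    return tags


def load_lexicon(
    path: str | Path,
    fmt: str | None = None,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    version: str | None = None,
) -> Lexicon:
    """Load a lexicon from a TSV (default) or CSV file.

    Columns: ``surface``, ``category``, ``tags`` (semicolon-separated
    ``key=value`` pairs, ``-`` for none). Duplicate (surface, category) rows
    collapse to one with a logged warning; unknown categories and malformed
    tags raise :class:`LexiconError` naming the line.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    delim = "," if fmt == "csv" else "\t"
    lex = Lexicon(version=version or path.stem, categories=categories)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not {"surface", "category"} <= set(
            reader.fieldnames
        ):
            raise LexiconError(f"{path}: header must name surface, category[, tags]")
        for lineno, row in enumerate(reader, start=2):
            surface = (row.get("surface") or "").strip()
            category = (row.get("category") or "").strip()
            if not surface:
                continue
            if category not in lex.categories:
                raise LexiconError(f"{path} line {lineno}: unknown category {category!r}")
            tags = _parse_tags(row.get("tags") or "", lineno)
            try:
                term = LexiconTerm.from_text(surface, category, tags)
            except LexiconError as exc:
                raise LexiconError(f"{path} line {lineno}: {exc}") from exc
            lex.add(term)
    return lex


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write in canonical order (surface, then category) — load∘save stable."""
    rows = sorted(lexicon.terms, key=lambda t: (t.text, t.category))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["surface", "category", "tags"])
        for t in rows:
            tag_str = ";".join(f"{k}={v}" for k, v in sorted(t.tags.items())) or "-"
            writer.writerow([t.text, t.category, tag_str])


@dataclass(frozen=True)
class TermMatch:
    """A lexicon term matched over a half-open token span."""

    term: LexiconTerm
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def match_terms(tokens: Sequence[str], lexicon: Lexicon) -> list[TermMatch]:
    """Greedy longest-match, left to right, with confusion-term suppression.

    Confusion-term matches are emitted (for audit) but any non-confusion
    match whose span lies fully inside a confusion span is dropped. At equal
    length and start, the category registry order breaks ties.
    """
    tokens = [t.lower() for t in tokens]
    by_surface: dict[tuple[str, ...], list[LexiconTerm]] = defaultdict(list)
    for term in lexicon.terms:
        by_surface[term.surface].append(term)
    max_len = min(MAX_TERM_TOKENS, max((len(s) for s in by_surface), default=0))

    # Pass 1: confusion spans, greedy longest-match over confusion terms only.
    confusion_spans: list[tuple[int, int]] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            cand = tuple(tokens[i : i + length])
            if any(
                t.category == CONFUSION_CATEGORY for t in by_surface.get(cand, ())
            ):
                hit = length
                break
        if hit:
            confusion_spans.append((i, i + hit))
            i += hit
        else:
            i += 1

    def suppressed(start: int, end: int) -> bool:
        return any(cs <= start and end <= ce for cs, ce in confusion_spans)

    # Pass 2: greedy longest-match over everything; suppression applied to
    # non-confusion matches contained in a confusion span.
    matches: list[TermMatch] = []
    i = 0
    while i < n:
        best: LexiconTerm | None = None
        best_len = 0
        for length in range(min(max_len, n - i), 0, -1):
            cands = by_surface.get(tuple(tokens[i : i + length]), ())
            viable = [
                t
                for t in cands
                if t.category == CONFUSION_CATEGORY or not suppressed(i, i + length)
            ]
            if viable:
                best = min(viable, key=lambda t: lexicon.category_rank(t.category))
                best_len = length
                break
        if best is not None:
            matches.append(TermMatch(best, i, i + best_len))
            i += best_len
        else:
            i += 1
    return matches


def score_candidate_terms(
    corpus: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
    max_len: int = MAX_TERM_TOKENS,
    min_cases: int = 3,
) -> list[tuple[str, str, float]]:
    """Rank candidate lexicon terms by an intent-specificity frequency ratio.

    For each n-gram (1..max_len tokens) and each intent class, the score is
    the fraction of that intent's cases containing the term divided by the
    fraction of all cases containing it. A term unique to a class that makes
    up 10% of the corpus therefore scores 10 for that class; a term spread
    uniformly scores 1 everywhere. Terms appearing in fewer than *min_cases*
    cases are dropped. Output is sorted by descending score, then term.

    *corpus* maps case id -> (text, intent label), or is a sequence of
    (text, intent) pairs.
    """
    if isinstance(corpus, Mapping):
        items = list(corpus.values())
    else:
        items = list(corpus)
    intents = {intent for _, intent in items}
    if len(intents) < 2:
        raise ValueError("candidate scoring needs at least 2 intent classes")

    n_total = len(items)
    n_by_intent = Counter(intent for _, intent in items)
    case_count: Counter[tuple[str, ...]] = Counter()
    class_count: dict[str, Counter] = {c: Counter() for c in intents}
    for text, intent in items:
        toks = tokenize(text)
        grams = {
            tuple(toks[i : i + k])
            for k in range(1, max_len + 1)
            for i in range(len(toks) - k + 1)
        }
        for g in grams:
            case_count[g] += 1
            class_count[intent][g] += 1

    out: list[tuple[str, str, float]] = []
    for gram, total in case_count.items():
        if total < min_cases:
            continue
        overall = total / n_total
        for intent in intents:
            rel = class_count[intent][gram] / n_by_intent[intent]
            out.append((" ".join(gram), intent, rel / overall))
    out.sort(key=lambda r: (-r[2], r[0], r[1]))
    return out
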