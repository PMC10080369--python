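"""Note segmentation, context-aware term extraction, per-case aggregation.

This is the term-extraction stage of the pipeline: notes are tiled into
sections, split into sentences, matched against the lexicon, and each match
is annotated with clinical context modifiers — negation ("denies SI"),
historical status ("GSW 10 years ago"), and non-patient subject ("brother
was shot"). Per-case extractions union mentions across all of the case's
notes; information density is measured as the number of unique
(term, context-signature) pairs, which is deliberately invariant to
verbatim duplication of notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .lexicon import CONFUSION_CATEGORY, Lexicon, LexiconTerm, load_lexicon, match_terms
from .tokenization import Token, split_sentences, tokenize_with_spans

DEFAULT_SECTION_HEADERS = (
    "HPI",
    "HISTORY",
    "PMH",
    "ED COURSE",
    "EXAM",
    "ASSESSMENT",
    "IMPRESSION",
    "PLAN",
)


@dataclass
class Sentence:
    """A sentence within one section of a note."""

    index: int
    section: str
    text: str
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)


@dataclass
class ClinicalNote:
    case_id: str
    note_type: str
    text: str
    date: str = ""
    sections: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def segmented(self) -> bool:
        return bool(self.sections)


@dataclass(frozen=True)
class TermMention:
    """One lexicon term matched in one sentence, with context modifiers."""

    term: LexiconTerm
    note_index: int
    sentence_index: int
    section: str
    negated: bool = False
    historical: bool = False
    other_subject: bool = False

    @property
    def sentence_id(self) -> tuple[int, int]:
        return (self.note_index, self.sentence_index)

    def context_signature(self) -> tuple:
        """(section, negated, historical, other_subject) — the identity used
        for unique-pair counting, chosen so that duplicated sentences do not
        add information."""
        return (self.section, self.negated, self.historical, self.other_subject)

    def pair_key(self) -> tuple:
        return (self.term.text, self.term.category, *self.context_signature())


@dataclass
class CaseExtraction:
    case_id: str
    mentions: list[TermMention] = field(default_factory=list)
    shooting_events: list = field(default_factory=list)  # list[ShootingEvent]
    n_notes: int = 0


@dataclass
class ContextConfig:
    """Trigger token-sequences and scope windows for modifier detection.

    Negation and other-subject triggers scope forward over the following
    *window* tokens of the same sentence; history triggers scope in both
    directions (clinical style puts "years ago" after the condition). A
    scope terminator between trigger and term cancels the modifier.
    """

    negation: tuple[tuple[str, ...], ...] = ()
    history: tuple[tuple[str, ...], ...] = ()
    other_subject: tuple[tuple[str, ...], ...] = ()
    terminators: tuple[tuple[str, ...], ...] = ()
    window: int = 6

    @classmethod
    def from_lexicon(cls, lex: Lexicon, window: int = 6) -> "ContextConfig":
        return cls(
            negation=tuple(lex.surfaces_of_category("negation_trigger")),
            history=tuple(lex.surfaces_of_category("history_trigger")),
            other_subject=tuple(lex.surfaces_of_category("other_subject_trigger")),
            terminators=tuple(lex.surfaces_of_category("scope_terminator")),
            window=window,
        )

    @classmethod
    def from_file(cls, path: str | Path, window: int = 6) -> "ContextConfig":
        return cls.from_lexicon(load_lexicon(path), window=window)


def segment_note(
    note: ClinicalNote,
    section_headers: Sequence[str] = DEFAULT_SECTION_HEADERS,
) -> ClinicalNote:
    """Tile the note text into sections and find sentence boundaries.

    A section starts at ``HEADER:`` (case-insensitive, headers from the
    configured list) and runs to the next header or end of text; text before
    the first header is the "preamble" section. Every character belongs to
    exactly one section.
    """
    text = note.text
    starts: list[tuple[int, str]] = []
    lower = text.lower()
    for header in section_headers:
        needle = header.lower() + ":"
        pos = 0
        while True:
            idx = lower.find(needle, pos)
            if idx < 0:
                break
            # header must start the text or follow whitespace/newline
            if idx == 0 or text[idx - 1] in " \n\t":
                starts.append((idx, header))
            pos = idx + 1
    starts.sort()

    sections: list[tuple[str, tuple[int, int]]] = []
    if not starts or starts[0][0] > 0:
        first_end = starts[0][0] if starts else len(text)
        sections.append(("preamble", (0, first_end)))
    for k, (pos, header) in enumerate(starts):
        end = starts[k + 1][0] if k + 1 < len(starts) else len(text)
        sections.append((header, (pos, end)))

    sentences: list[Sentence] = []
    for header, (s_start, s_end) in sections:
        body = text[s_start:s_end]
        for sent_start, sent_end in split_sentences(body):
            abs_start, abs_end = s_start + sent_start, s_start + sent_end
            sent_text = text[abs_start:abs_end]
            sentences.append(
                Sentence(
                    index=len(sentences),
                    section=header,
                    text=sent_text,
                    start=abs_start,
                    end=abs_end,
                    tokens=tokenize_with_spans(sent_text),
                )
            )
    return replace(note, sections=sections, sentences=sentences)


def _trigger_positions(
    tokens: list[str], triggers: tuple[tuple[str, ...], ...]
) -> list[tuple[int, int]]:
    """Spans (start, end) of every trigger occurrence in the token list."""
    out = []
    for trig in triggers:
        k = len(trig)
        for i in range(len(tokens) - k + 1):
            if tuple(tokens[i : i + k]) == trig:
                out.append((i, i + k))
    return out


def _in_scope_before(
    trig_spans: list[tuple[int, int]],
    term_spans: list[tuple[int, int]],
    match_start: int,
    window: int,
) -> bool:
    for ts, te in trig_spans:
        if te <= match_start and match_start - te <= window:
            if not any(te <= s and e <= match_start for s, e in term_spans):
                return True
    return False


def _in_scope_after(
    trig_spans: list[tuple[int, int]],
    term_spans: list[tuple[int, int]],
    match_end: int,
    window: int,
) -> bool:
    for ts, te in trig_spans:
        if ts >= match_end and ts - match_end <= window:
            if not any(match_end <= s and e <= ts for s, e in term_spans):
                return True
    return False


def extract_mentions(
    note: ClinicalNote,
    lexicon: Lexicon,
    context: ContextConfig,
    note_index: int = 0,
) -> list[TermMention]:
    """Match lexicon terms sentence by sentence and attach context modifiers.

    Confusion-term matches are consumed for suppression but never become
    mentions — they carry no intent signal downstream.
    """
    if not note.segmented:
        note = segment_note(note)
    mentions: list[TermMention] = []
    for sent in note.sentences:
        toks = [t.text for t in sent.tokens]
        neg_spans = _trigger_positions(toks, context.negation)
        hist_spans = _trigger_positions(toks, context.history)
        subj_spans = _trigger_positions(toks, context.other_subject)
        term_spans = _trigger_positions(toks, context.terminators)
        for m in match_terms(toks, lexicon):
            if m.term.category == CONFUSION_CATEGORY:
                continue
            negated = _in_scope_before(neg_spans, term_spans, m.start, context.window)
            historical = _in_scope_before(
                hist_spans, term_spans, m.start, context.window
            ) or _in_scope_after(hist_spans, term_spans, m.end, context.window)
            other = _in_scope_before(subj_spans, term_spans, m.start, context.window)
            mentions.append(
                TermMention(
                    term=m.term,
                    note_index=note_index,
                    sentence_index=sent.index,
                    section=sent.section,
                    negated=negated,
                    historical=historical,
                    other_subject=other,
                )
            )
    return mentions


def aggregate_case(
    notes: Sequence[ClinicalNote],
    lexicon: Lexicon,
    context: ContextConfig,
    parser=None,
    shooting_verbs: Iterable[tuple[str, ...]] | None = None,
) -> CaseExtraction:
    """Union mentions (and shooting events, if a parser is given) over all
    of a case's notes, in note order."""
    if not notes:
        raise ValueError("aggregate_case needs at least one note")
    case_ids = {n.case_id for n in notes}
    if len(case_ids) != 1:
        raise ValueError(f"mixed case_ids in aggregate_case: {sorted(case_ids)}")

    extraction = CaseExtraction(case_id=notes[0].case_id, n_notes=len(notes))
    from .dependency import events_for_note  # local import: avoid cycle

    if shooting_verbs is None:
        shooting_verbs = lexicon.surfaces_of_category("shooting_verb")
    verbs = set(shooting_verbs)
    for idx, note in enumerate(notes):
        if not note.segmented:
            note = segment_note(note)
        extraction.mentions.extend(extract_mentions(note, lexicon, context, idx))
        if parser is not None:
            extraction.shooting_events.extend(events_for_note(note, parser, verbs))
    return extraction


def count_unique_term_context_pairs(
    x: CaseExtraction, scope: str = "per_case"
) -> int | list[int]:
    """Number of distinct (term, context-signature) pairs.

    ``per_case`` → one count over all mentions; ``per_note`` → list of
    per-note counts (the high-info-note rule takes the max of these).
    """
    if scope == "per_case":
        return len({m.pair_key() for m in x.mentions})
    if scope == "per_note":
        counts = []
        for i in range(x.n_notes):
            counts.append(
                len({m.pair_key() for m in x.mentions if m.note_index == i})
            )
        return counts
    raise ValueError(f"unknown scope {scope!r}")
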