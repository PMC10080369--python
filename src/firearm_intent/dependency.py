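"""Shooter / person-shot / circumstance extraction from dependency arcs.

Role extraction consumes a :class:`ParsedSentence` — tokens plus labelled
head-dependent arcs — produced by any parser provider (a callable
``tokens -> ParsedSentence``). Two providers ship with the package:

* :class:`PatternParser` — a deterministic pattern-based parser for the
  clause shapes that dominate clinical shooting narratives ("pt shot
  himself in the chest", "he was shot by police during an altercation").
* :class:`FixtureParser` — replays gold parses from a JSON file; used in
  tests so role extraction is checked against known arcs.

Role logic: in active voice the ``nsubj`` child of a shooting verb is the
shooter and the ``obj``/``dobj`` child the person shot; in passive voice
(``nsubjpass``/``nsubj:pass`` present) the passive subject is the person
shot and the ``agent``/``obl:agent`` phrase the shooter. Adverbial modifiers
and prepositional subtrees become circumstance phrases. A reflexive person
shot ("himself") with a shooter present marks the event self-directed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

RELATION_INVENTORY = frozenset(
    {
        "root",
        "nsubj",
        "nsubjpass",
        "nsubj:pass",
        "dobj",
        "obj",
        "agent",
        "obl:agent",
        "advmod",
        "prep",
        "obl",
        "pobj",
        "aux",
        "auxpass",
        "det",
        "amod",
        "compound",
        "case",
        "dep",
    }
)

REFLEXIVES = frozenset({"himself", "herself", "themselves", "myself", "itself"})

PASSIVE_SUBJECT = {"nsubjpass", "nsubj:pass"}
OBJECT_RELS = {"dobj", "obj"}
AGENT_RELS = {"agent", "obl:agent"}
OBLIQUE_RELS = {"prep", "obl"}

MAX_CIRCUMSTANCE_TOKENS = 8


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class Arc:
    dependent: int
    head: int
    relation: str


@dataclass
class ParsedSentence:
    """Tokens plus dependency arcs; exactly one root, acyclic."""

    tokens: list[str]
    arcs: list[Arc]

    def __post_init__(self) -> None:
        self.arcs = [a if isinstance(a, Arc) else Arc(*a) for a in self.arcs]
        if not self.tokens:
            raise ParseError("empty sentence")
        n = len(self.tokens)
        roots = [a for a in self.arcs if a.relation == "root"]
        if len(roots) != 1:
            raise ParseError(f"expected exactly 1 root, got {len(roots)}")
        heads: dict[int, int] = {}
        for a in self.arcs:
            if a.relation not in RELATION_INVENTORY:
                raise ParseError(f"relation {a.relation!r} not in inventory")
            if not (0 <= a.dependent < n):
                raise ParseError(f"arc dependent {a.dependent} out of range")
            if a.relation != "root" and not (0 <= a.head < n):
                raise ParseError(f"arc head {a.head} out of range")
            if a.dependent in heads:
                raise ParseError(f"token {a.dependent} has two heads")
            heads[a.dependent] = a.head if a.relation != "root" else -1
        # cycle check by walking to root from every node
        for start in heads:
            seen = set()
            node = start
            while node != -1:
                if node in seen:
                    raise ParseError("cyclic arcs")
                seen.add(node)
                node = heads.get(node, -1)

    def children(self, head: int, relations: Iterable[str] | None = None) -> list[Arc]:
        rels = set(relations) if relations is not None else None
        return [
            a
            for a in self.arcs
            if a.head == head
            and a.relation != "root"
            and (rels is None or a.relation in rels)
        ]

    def subtree(
        self, index: int, drop_relations: frozenset[str] = frozenset()
    ) -> list[int]:
        """Token indices of the subtree rooted at *index*, in order."""
        kids: dict[int, list[int]] = {}
        for a in self.arcs:
            if a.relation != "root" and a.relation not in drop_relations:
                kids.setdefault(a.head, []).append(a.dependent)
        out: list[int] = []
        stack = [index]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(kids.get(node, ()))
        return sorted(set(out))

    def phrase(
        self,
        index: int,
        max_tokens: int | None = None,
        drop_relations: frozenset[str] = frozenset(),
    ) -> str:
        idxs = self.subtree(index, drop_relations)
        if max_tokens is not None:
            idxs = idxs[:max_tokens]
        return " ".join(self.tokens[i] for i in idxs)


ParserProvider = Callable[[Sequence[str]], ParsedSentence]


@dataclass
class ShootingEvent:
    """Roles extracted around one shooting-verb token."""

    verb: str
    verb_index: int
    shooter: str | None = None
    shot_person: str | None = None
    circumstances: list[str] = field(default_factory=list)
    passive: bool = False
    self_directed: bool = False
    sentence_id: tuple[int, int] = (0, 0)
    sentence_text: str = ""


def extract_events(
    parsed: ParsedSentence, shooting_verbs: Iterable[tuple[str, ...]] | Iterable[str]
) -> list[ShootingEvent]:
    """Build a :class:`ShootingEvent` for every shooting-verb token that has
    at least one role or circumstance attached."""
    verb_forms = set()
    for v in shooting_verbs:
        verb_forms.add(v[0] if isinstance(v, tuple) else str(v).lower())

    events: list[ShootingEvent] = []
    for i, tok in enumerate(parsed.tokens):
        if tok.lower() not in verb_forms:
            continue
        passive_subj = parsed.children(i, PASSIVE_SUBJECT)
        passive = bool(passive_subj)
        shooter_idx: int | None = None
        shot_idx: int | None = None
        if passive:
            shot_idx = passive_subj[0].dependent
            agents = parsed.children(i, AGENT_RELS)
            if agents:
                shooter_idx = agents[0].dependent
        else:
            subj = parsed.children(i, {"nsubj"})
            obj = parsed.children(i, OBJECT_RELS)
            if subj:
                shooter_idx = subj[0].dependent
            if obj:
                shot_idx = obj[0].dependent

        circumstances: list[str] = []
        for a in parsed.children(i, {"advmod"}):
            circumstances.append(parsed.tokens[a.dependent])
        for a in parsed.children(i, OBLIQUE_RELS):
            if a.dependent in (shooter_idx,):
                continue
            circumstances.append(parsed.phrase(a.dependent, MAX_CIRCUMSTANCE_TOKENS))

        if shooter_idx is None and shot_idx is None and not circumstances:
            continue

        role_drop = frozenset({"case"})  # "by" marker is not part of the role
        shot_text = (
            parsed.phrase(shot_idx, MAX_CIRCUMSTANCE_TOKENS, role_drop)
            if shot_idx is not None
            else None
        )
        self_directed = (
            shot_idx is not None
            and parsed.tokens[shot_idx].lower() in REFLEXIVES
            and shooter_idx is not None
        )
        events.append(
            ShootingEvent(
                verb=tok,
                verb_index=i,
                shooter=(
                    parsed.phrase(shooter_idx, MAX_CIRCUMSTANCE_TOKENS, role_drop)
                    if shooter_idx is not None
                    else None
                ),
                shot_person=shot_text,
                circumstances=circumstances,
                passive=passive,
                self_directed=self_directed,
            )
        )
    return events


def events_for_note(note, parser: ParserProvider, shooting_verbs) -> list[ShootingEvent]:
    """Parse each sentence of a segmented note that contains a shooting verb
    and extract events; a failing parse skips the sentence with a warning."""
    import logging

    logger = logging.getLogger(__name__)
    verb_forms = {v[0] if isinstance(v, tuple) else str(v).lower() for v in shooting_verbs}
    out: list[ShootingEvent] = []
    for sent in note.sentences:
        toks = [t.text for t in sent.tokens]
        if not verb_forms & set(toks):
            continue
        try:
            parsed = parser(toks)
        except Exception as exc:  # provider failure -> skip, no event
            logger.warning("parse failed on %r: %s", sent.text, exc)
            continue
        for ev in extract_events(parsed, verb_forms):
            ev.sentence_id = (0, sent.index)
            ev.sentence_text = sent.text
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Parser providers


class FixtureParser:
    """Replays gold parses from JSON: {"sentences": [{"tokens": [...],
    "arcs": [[dep, head, rel], ...]}, ...]} keyed by the joined token string."""

    def __init__(self, path: str | Path | None = None, parses: dict | None = None):
        self._parses: dict[str, ParsedSentence] = {}
        records = []
        if path is not None:
            records = json.loads(Path(path).read_text())["sentences"]
        if parses is not None:
            records = list(records) + list(parses)
        for rec in records:
            key = " ".join(t.lower() for t in rec["tokens"])
            self._parses[key] = ParsedSentence(
                [t.lower() for t in rec["tokens"]],
                [Arc(*a) for a in rec["arcs"]],
            )

    def __call__(self, tokens: Sequence[str]) -> ParsedSentence:
        key = " ".join(t.lower() for t in tokens)
        if key not in self._parses:
            raise ParseError(f"no gold parse for {key!r}")
        return self._parses[key]


_PRONOUNS = frozenset(
    {"he", "she", "they", "pt", "patient", "i", "we", "who", "man", "woman"}
)
_AUX = frozenset({"was", "were", "is", "been", "being", "be", "got", "getting"})
_PREPOSITIONS = frozenset(
    {"in", "at", "on", "near", "during", "while", "with", "outside", "inside", "after", "to"}
)
_STOP_SUBJECT = frozenset({"the", "a", "an", "and", ",", "."})


class PatternParser:
    """Deterministic dependency parser for simple shooting-clause patterns.

    Handles active ("X shot Y ..."), passive ("X was shot by Y ..."),
    agentless passive, adverb-verb pairs ("accidentally discharged"), and
    trailing prepositional phrases. Anything it cannot attach hangs off the
    root with the ``dep`` relation, so the output always satisfies the
    single-root acyclic contract.
    """

    def __init__(self, shooting_verbs: Iterable[str] = ("shot", "fired", "discharged")):
        self.verbs = {str(v).lower() for v in shooting_verbs}

    def __call__(self, tokens: Sequence[str]) -> ParsedSentence:
        toks = [t.lower() for t in tokens]
        if not toks:
            raise ParseError("empty sentence")
        n = len(toks)
        verb_idx = next((i for i, t in enumerate(toks) if t in self.verbs), None)
        root = verb_idx if verb_idx is not None else 0
        attached: dict[int, tuple[int, str]] = {}

        def attach(dep: int, head: int, rel: str) -> None:
            if dep != root and dep not in attached:
                attached[dep] = (head, rel)

        if verb_idx is not None:
            i = verb_idx
            # passive: auxiliary within 3 tokens before the verb
            aux_idx = next(
                (j for j in range(max(0, i - 3), i) if toks[j] in _AUX), None
            )
            passive = aux_idx is not None
            if passive:
                attach(aux_idx, i, "auxpass")
            # subject: nearest noun-ish token before aux/verb
            limit = aux_idx if passive else i
            subj_idx = next(
                (
                    j
                    for j in range(limit - 1, -1, -1)
                    if toks[j] not in _STOP_SUBJECT
                    and toks[j] not in _AUX
                    and not toks[j].endswith("ly")
                ),
                None,
            )
            if subj_idx is not None and toks[subj_idx] not in _PREPOSITIONS:
                attach(subj_idx, i, "nsubjpass" if passive else "nsubj")
                # determiner/compound inside the subject phrase
                for j in range(subj_idx - 1, -1, -1):
                    if toks[j] in {"the", "a", "an"}:
                        attach(j, subj_idx, "det")
                        break
                    if toks[j] in _STOP_SUBJECT or toks[j] in _PREPOSITIONS:
                        break
                    attach(j, subj_idx, "compound")
            # adverb directly before the verb
            if i >= 1 and toks[i - 1].endswith("ly"):
                attach(i - 1, i, "advmod")
            # right side: agent ("by X"), object, prepositional phrases
            j = i + 1
            took_object = False
            while j < n:
                t = toks[j]
                if t == "by" and passive:
                    k = self._phrase_head(toks, j + 1)
                    if k is not None:
                        attach(k, i, "agent")
                        attach(j, k, "case")
                        self._attach_phrase(toks, j + 1, k, attach)
                        j = self._phrase_end(toks, j + 1)
                        continue
                if t in _PREPOSITIONS:
                    k = self._phrase_head(toks, j + 1)
                    if k is not None:
                        attach(k, i, "obl")
                        attach(j, k, "case")
                        self._attach_phrase(toks, j + 1, k, attach)
                        j = self._phrase_end(toks, j + 1)
                        continue
                    attach(j, i, "dep")
                    j += 1
                    continue
                if (
                    not passive
                    and not took_object
                    and t not in _STOP_SUBJECT
                    and t.isalpha()
                ):
                    attach(j, i, "obj")
                    took_object = True
                    j += 1
                    continue
                attach(j, i, "dep")
                j += 1

        arcs = [Arc(root, -1, "root")]
        for dep in range(n):
            if dep == root:
                continue
            head, rel = attached.get(dep, (root, "dep"))
            arcs.append(Arc(dep, head, rel))
        return ParsedSentence(list(toks), arcs)

    @staticmethod
    def _phrase_head(toks: list[str], start: int) -> int | None:
        """Head of the noun phrase starting at *start*: its last alpha token
        before the next preposition/punctuation."""
        end = PatternParser._phrase_end(toks, start)
        for j in range(end - 1, start - 1, -1):
            if toks[j].isalnum() and toks[j] not in {"the", "a", "an"}:
                return j
        return None

    @staticmethod
    def _phrase_end(toks: list[str], start: int) -> int:
        j = start
        while j < len(toks) and toks[j] not in _PREPOSITIONS and toks[j] not in {
            ",",
            ".",
            ";",
            "!",
            "?",
            "by",
        }:
            j += 1
        return j

    @staticmethod
    def _attach_phrase(toks, start, head, attach) -> None:
        end = PatternParser._phrase_end(toks, start)
        for j in range(start, end):
            if j != head:
                attach(j, head, "det" if toks[j] in {"the", "a", "an"} else "compound")
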