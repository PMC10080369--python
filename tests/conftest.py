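"""Shared fixtures: default resources, the rule-engine oracle suite, and
gold dependency parses."""

from __future__ import annotations

import pytest

from firearm_intent import (
    ContextConfig,
    FixtureParser,
    default_context,
    default_lexicon,
    default_parser,
    default_rules,
)
from firearm_intent.extraction import ClinicalNote, aggregate_case


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def context() -> ContextConfig:
    return default_context()


@pytest.fixture(scope="session")
def parser():
    return default_parser()


@pytest.fixture(scope="session")
def ruleset():
    return default_rules()


FEATURE_ORDER = [
    "explicit_accident", "explicit_assault", "explicit_self_harm",
    "explicit_legal", "no_info_attestation", "assault_shooter",
    "legal_shooter", "self_directed_shot", "location_inside",
    "location_outside", "high_info_note", "low_info_case",
    "no_explicit_intent", "conflicting_intent",
]

# Hand-built oracle: case id -> (note texts, expected feature vector in
# FEATURE_ORDER). Derived by hand from the default lexicon, the default
# thresholds (high=5, low=3) and the rule definitions.
RULE_ORACLE: dict[str, tuple[list[str], list[int]]] = {
    "r01": (["Pt reports this was a suicide attempt."],
            [0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0]),
    "r02": (["Denies suicide attempt."],
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0]),
    "r03": (["Patient shot himself in the chest."],
            [0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0]),
    "r04": (["He was shot by police."],
            [0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 1, 0]),
    "r05": (["He was shot by another man during an altercation."],
            [0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0]),
    "r06": (["The gun accidentally discharged while cleaning."],
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0]),
    "r07": (["Per police report pt was shot."],
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0]),
    "r08": (["Pt was shot at home."],
            [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 1, 1, 0]),
    "r09": (["Pt was shot in the street during a robbery."],
            [0, 1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0]),
    "r10": (["Circumstances of shooting unknown."],
            [0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0]),
    "r11": (["Pt was shot during a robbery. Self inflicted gunshot wound noted."],
            [0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1]),
    "r12": (["GSW to left leg. Handgun recovered. Pt was shot in the street. "
             "A bullet was found. Single gunshot wound noted."],
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 1, 0]),
    "r13": (["GSW to left leg. Handgun recovered. A bullet was found. "
             "Pt found at home. Single gunshot wound noted."],
            [0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 1, 0]),
    "r14": (["GSW to left leg.", "GSW to left leg."],
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0]),
    "r15": (["Vitals stable on arrival."],
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0]),
}


def build_case(case_id, note_texts, lexicon, context, parser):
    notes = [
        ClinicalNote(case_id=case_id, note_type="ED note", text=t)
        for t in note_texts
    ]
    return aggregate_case(notes, lexicon, context, parser=parser)


@pytest.fixture(scope="session")
def oracle_cases(lexicon, context, parser):
    """CaseExtraction per oracle id, built through the real extraction path."""
    return {
        cid: build_case(cid, texts, lexicon, context, parser)
        for cid, (texts, _) in RULE_ORACLE.items()
    }


# Gold dependency parses (the fixture-parser contract).
GOLD_PARSES = {
    "sentences": [
        {
            "tokens": ["he", "shot", "himself"],
            "arcs": [[1, -1, "root"], [0, 1, "nsubj"], [2, 1, "obj"]],
        },
        {
            "tokens": ["patient", "shot", "himself", "in", "the", "chest"],
            "arcs": [
                [1, -1, "root"], [0, 1, "nsubj"], [2, 1, "obj"],
                [5, 1, "obl"], [3, 5, "case"], [4, 5, "det"],
            ],
        },
        {
            "tokens": ["he", "was", "shot", "by", "police"],
            "arcs": [
                [2, -1, "root"], [0, 2, "nsubjpass"], [1, 2, "auxpass"],
                [4, 2, "agent"], [3, 4, "case"],
            ],
        },
        {
            "tokens": ["police", "shot", "he"],
            "arcs": [[1, -1, "root"], [0, 1, "nsubj"], [2, 1, "obj"]],
        },
        {
            "tokens": ["he", "was", "shot", "by", "police", "!"],
            "arcs": [
                [2, -1, "root"], [0, 2, "nsubjpass"], [1, 2, "auxpass"],
                [4, 2, "agent"], [3, 4, "case"], [5, 2, "dep"],
            ],
        },
        {
            "tokens": ["the", "shot", "hurt"],
            "arcs": [[1, -1, "root"], [0, 1, "det"], [2, 1, "dep"]],
        },
    ]
}


@pytest.fixture(scope="session")
def fixture_parser():
    return FixtureParser(parses=GOLD_PARSES["sentences"])
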