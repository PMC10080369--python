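"""Synthetic multi-note firearm-injury cases with a generation-log oracle.

Real gunshot-injury EHR data cannot be shared, so this module generates
labelled cases from a small template grammar. Every construct the pipeline
must detect is emitted deliberately and recorded in a per-case generation
log: explicit intent cues, shooter/person-shot clauses, negated and
historical distractors, confusion-term traps, no-information attestations,
and site-dependent documentation density. Tests therefore check extraction
and rule outputs against the log, not against the rendered prose.

A :class:`SiteProfile` controls the adjudicated-intent mix, the ICD
miscoding behaviour of hospital coders (a row-stochastic matrix from true
intent to coded intent), documentation density per intent, and cue strength.
The default profiles mirror a development site (assault-heavy, many
unknown-intent cases with sparse notes) and an external-validation-like site
(more self-harm and accidents, uniformly dense notes).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .evaluation import CLASS_ORDER
from .extraction import ClinicalNote

INTENTS = CLASS_ORDER


class ProfileError(ValueError):
    pass


def miscoding_from_marginals(
    true_p: Sequence[float], icd_p: Sequence[float]
) -> np.ndarray:
    """Row-stochastic miscoding matrix that maps the true-intent marginal
    exactly onto the ICD-coded marginal.

    Classes whose true share exceeds their coded share donate the surplus;
    donations are allocated to deficit classes in proportion to each
    deficit. With the published marginals this moves excess assault-truth
    mass into ICD-coded accident — the documented inflation pattern.
    """
    t = np.asarray(true_p, dtype=float)
    c = np.asarray(icd_p, dtype=float)
    if t.shape != c.shape or len(t) != len(INTENTS):
        raise ProfileError("marginals must both have 5 classes")
    t = t / t.sum()
    c = c / c.sum()
    diff = t - c  # positive = surplus (donor), negative = deficit (recipient)
    deficits = np.clip(-diff, 0, None)
    total_deficit = deficits.sum()
    M = np.eye(len(t))
    if total_deficit <= 0:
        return M
    share = deficits / total_deficit
    for d in range(len(t)):
        if diff[d] > 0 and t[d] > 0:
            donated = diff[d]
            M[d, d] = (t[d] - donated) / t[d]
            M[d] += (donated / t[d]) * share  # share[d] = 0 for donors
    return M


@dataclass
class SiteProfile:
    """Generation parameters for one hospital site."""

    name: str
    intent_distribution: dict[str, float]
    icd_miscoding: np.ndarray
    notes_per_case: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.45, 3: 0.20}
    )
    cue_strength: dict[str, float] = field(
        default_factory=lambda: {
            # not every chart documents the circumstance; legal-intervention
            # narratives are the least consistently written out
            "accident": 0.85,
            "assault": 0.90,
            "legal_intervention": 0.70,
            "self_harm": 0.85,
            "unknown": 0.30,  # most unknown cases simply lack information
        }
    )
    #: mean informative (lexicon-term-bearing) sentences per case, by intent
    info_density: dict[str, float] = field(
        default_factory=lambda: {
            "accident": 7.0,
            "assault": 7.0,
            "legal_intervention": 7.0,
            "self_harm": 7.0,
            "unknown": 1.0,
        }
    )
    filler_density: float = 3.0  # mean filler sentences per note
    distractor_rate: float = 0.5
    redundancy: int = 1  # verbatim copies of each informative sentence

    def __post_init__(self) -> None:
        p = np.array([self.intent_distribution.get(c, 0.0) for c in INTENTS])
        # published marginals are rounded percentages; allow that slack and
        # normalize at draw time
        if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=5e-3):
            raise ProfileError("intent_distribution must be a distribution over 5 intents")
        self.icd_miscoding = np.asarray(self.icd_miscoding, dtype=float)
        if self.icd_miscoding.shape != (5, 5) or not np.allclose(
            self.icd_miscoding.sum(axis=1), 1.0, atol=1e-6
        ):
            raise ProfileError("icd_miscoding must be 5x5 row-stochastic")
        if self.redundancy < 1:
            raise ProfileError("redundancy must be >= 1")
        q = np.array(list(self.notes_per_case.values()))
        if not np.isclose(q.sum(), 1.0, atol=1e-6):
            raise ProfileError("notes_per_case must be a distribution")


# Adjudicated and ICD-coded intent mixes observed at the two study-like sites.
MDS_TRUE = (0.075, 0.708, 0.018, 0.054, 0.145)
MDS_ICD = (0.235, 0.569, 0.011, 0.048, 0.137)
EVS_TRUE = (0.148, 0.664, 0.036, 0.114, 0.036)
EVS_ICD = (0.339, 0.482, 0.030, 0.111, 0.038)


def mds_profile() -> SiteProfile:
    return SiteProfile(
        name="mds",
        intent_distribution=dict(zip(INTENTS, MDS_TRUE)),
        icd_miscoding=miscoding_from_marginals(MDS_TRUE, MDS_ICD),
    )


def evs_profile() -> SiteProfile:
    """External-validation-like site: denser, more self-harm/accidents, and
    uniform documentation density (every case reads as a high-info note)."""
    return SiteProfile(
        name="evs",
        intent_distribution=dict(zip(INTENTS, EVS_TRUE)),
        icd_miscoding=miscoding_from_marginals(EVS_TRUE, EVS_ICD),
        info_density={c: 7.0 for c in INTENTS},
        cue_strength={
            "accident": 0.85,
            "assault": 0.90,
            "legal_intervention": 0.70,
            "self_harm": 0.85,
            "unknown": 0.95,  # unknowns are flagged explicitly, not by sparsity
        },
    )


def density_uniform_profile() -> SiteProfile:
    """MDS intent mix but no density separation — used to probe how much the
    classifier leans on the information-density rules."""
    p = mds_profile()
    return replace(
        p,
        name="density_uniform",
        info_density={c: 7.0 for c in INTENTS},
        cue_strength={**p.cue_strength, "unknown": 0.95},
    )


def drifted_profile(base: SiteProfile, redundancy_factor: int) -> SiteProfile:
    """Documentation drift: every informative sentence is written out
    *redundancy_factor* times, raising raw mention counts without adding any
    new unique (term, context) pair."""
    if redundancy_factor < 1:
        raise ProfileError("redundancy_factor must be >= 1")
    return replace(base, name=f"{base.name}_drift{redundancy_factor}",
                   redundancy=base.redundancy * redundancy_factor)


# ---------------------------------------------------------------------------
# Template grammar

# Intent cue sentences. Each entry: (text, markers) where markers name the
# constructs the pipeline is expected to recover from this sentence.
CUE_SENTENCES: dict[str, list[tuple[str, dict]]] = {
    "self_harm": [
        ("Patient shot himself in the chest.", {"event": "self_directed"}),
        ("Pt reports this was a suicide attempt.", {"explicit": "self_harm"}),
        ("Self inflicted gunshot wound to the head.", {"explicit": "self_harm"}),
    ],
    "assault": [
        ("He was shot by another man during an altercation.",
         {"event": "assault_shooter", "explicit": "assault"}),
        ("Pt was shot during a robbery.", {"explicit": "assault"}),
        ("The assailant fired at the patient.", {"explicit": "assault",
                                                 "event": "assault_shooter"}),
    ],
    "legal_intervention": [
        ("Pt was shot by police during the arrest.", {"event": "legal_shooter"}),
        ("This was an officer involved shooting.", {"explicit": "legal"}),
    ],
    "accident": [
        ("The gun accidentally discharged while cleaning.", {"explicit": "accident"}),
        ("Pt sustained an accidental discharge injury.", {"explicit": "accident"}),
    ],
    "unknown": [
        ("Circumstances of shooting unknown.", {"explicit": "unknown"}),
        ("Intent unclear at this time.", {"explicit": "unknown"}),
    ],
}

# Informative filler: each sentence carries a distinct lexicon pair but no
# explicit intent cue. Distractor entries exercise the context modifiers.
INFORMATIVE_SENTENCES: list[tuple[str, dict]] = [
    ("GSW to the left leg.", {"term": "gsw"}),
    ("Single gunshot wound noted on exam.", {"term": "gunshot wound"}),
    ("A handgun was recovered at the scene.", {"term": "handgun"}),
    ("The firearm was secured by EMS.", {"term": "firearm"}),
    ("Incident occurred in the street.", {"term": "in the street", "tag": "outside"}),
    ("Pt was found at home by family.", {"term": "at home", "tag": "inside"}),
    ("Shooting took place in a parking lot.", {"term": "parking lot", "tag": "outside"}),
    ("Bullet fragments seen on imaging.", {"term": "bullet"}),
    ("Wound consistent with gunshot injury.", {"term": "gunshot"}),
    ("Pt arrived by ambulance from the nightclub.", {"term": "nightclub", "tag": "inside"}),
    ("Denies suicidal ideation.", {"term": "suicidal ideation", "negated": True}),
    ("History of GSW 10 years ago.", {"term": "gsw", "historical": True}),
    ("Per police report pt sustained a GSW.", {"term": "gsw", "confusion_trap": True}),
    ("Brother states he heard the gunshot.", {"term": "gunshot", "other_subject": True}),
]

FILLER_SENTENCES = [
    "Vitals stable on arrival.",
    "Pain controlled with medication.",
    "Labs unremarkable.",
    "Imaging reviewed with radiology.",
    "Plan discussed with the team.",
    "Patient resting comfortably.",
    "Wound dressed and monitored.",
    "Tetanus status up to date.",
    "Social work consulted.",
    "Follow up arranged with clinic.",
]

NOTE_TYPES = ("ED note", "progress note", "discharge summary")


@dataclass
class GenerationRecord:
    """What the grammar actually emitted for one case — the test oracle."""

    cue_sentences: list[tuple[str, dict]] = field(default_factory=list)
    informative: list[tuple[str, dict]] = field(default_factory=list)
    n_informative: int = 0
    has_explicit_cue: bool = False
    has_event_cue: bool = False
    redundancy: int = 1


@dataclass
class SyntheticCase:
    case_id: str
    true_intent: str
    icd_intent: str
    notes: list[ClinicalNote]
    log: GenerationRecord


def render_note(
    true_intent: str,
    profile: SiteProfile,
    rng: np.random.Generator,
    case_id: str = "case",
    note_type: str = "ED note",
    informative: Sequence[tuple[str, dict]] = (),
) -> ClinicalNote:
    """Render one note: an HPI section holding the informative sentences
    (each written ``profile.redundancy`` times) and trailing sections of
    clinical filler."""
    if true_intent not in INTENTS:
        raise ProfileError(f"invalid intent {true_intent!r}")
    hpi: list[str] = []
    for text, _ in informative:
        hpi.extend([text] * profile.redundancy)
    n_filler = int(rng.poisson(profile.filler_density))
    filler = [FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))]
              for _ in range(n_filler)]
    parts = ["HPI:"]
    parts.extend(hpi if hpi else ["Patient presents to the ED."])
    parts.append("ED COURSE:")
    parts.extend(filler if filler else ["Course uneventful."])
    parts.append("ASSESSMENT:")
    parts.append("Injury as described above." if informative else "See note above.")
    return ClinicalNote(
        case_id=case_id, note_type=note_type, text="\n".join(parts)
    )


def _draw_case_content(
    true_intent: str, profile: SiteProfile, rng: np.random.Generator
) -> GenerationRecord:
    rec = GenerationRecord(redundancy=profile.redundancy)
    if rng.random() < profile.cue_strength[true_intent]:
        bank = CUE_SENTENCES[true_intent]
        cue = bank[int(rng.integers(len(bank)))]
        rec.cue_sentences.append(cue)
        rec.has_explicit_cue = "explicit" in cue[1]
        rec.has_event_cue = "event" in cue[1]
    mean = profile.info_density[true_intent]
    k = int(min(rng.poisson(mean), len(INFORMATIVE_SENTENCES)))
    if k:
        picks = rng.choice(len(INFORMATIVE_SENTENCES), size=k, replace=False)
        rec.informative = [INFORMATIVE_SENTENCES[i] for i in sorted(picks)]
    # distractors double as informative sentences; an extra one sometimes
    if rng.random() < profile.distractor_rate:
        distractors = [s for s in INFORMATIVE_SENTENCES
                       if s[1].get("negated") or s[1].get("historical")]
        d = distractors[int(rng.integers(len(distractors)))]
        if d not in rec.informative:
            rec.informative.append(d)
    rec.n_informative = len(rec.informative)
    return rec


def generate_corpus(
    n: int, profile: SiteProfile, seed: int = 0
) -> list[SyntheticCase]:
    """Generate *n* labelled cases; deterministic for a given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p_true = np.array([profile.intent_distribution[c] for c in INTENTS])
    p_true = p_true / p_true.sum()
    note_counts = sorted(profile.notes_per_case)
    p_notes = np.array([profile.notes_per_case[k] for k in note_counts])
    p_notes = p_notes / p_notes.sum()

    cases: list[SyntheticCase] = []
    for i in range(n):
        case_id = f"{profile.name}-{i:05d}"
        true_intent = INTENTS[int(rng.choice(5, p=p_true))]
        icd_intent = INTENTS[
            int(rng.choice(5, p=profile.icd_miscoding[INTENTS.index(true_intent)]))
        ]
        rec = _draw_case_content(true_intent, profile, rng)
        n_notes = int(note_counts[int(rng.choice(len(note_counts), p=p_notes))])
        notes: list[ClinicalNote] = []
        # all intent-bearing text lives in the first (ED) note; later notes
        # are progress/discharge filler
        first_content = list(rec.cue_sentences) + list(rec.informative)
        for j in range(n_notes):
            notes.append(
                render_note(
                    true_intent,
                    profile,
                    rng,
                    case_id=case_id,
                    note_type=NOTE_TYPES[min(j, len(NOTE_TYPES) - 1)],
                    informative=first_content if j == 0 else (),
                )
            )
        cases.append(SyntheticCase(case_id, true_intent, icd_intent, notes, rec))
    return cases


# ---------------------------------------------------------------------------
# File interchange (same formats the real-data path consumes)


def write_corpus(cases: Sequence[SyntheticCase], out_dir: str | Path) -> dict[str, Path]:
    """Write notes as JSON-lines and labels (adjudicated + ICD) as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    notes_path = out_dir / "notes.jsonl"
    labels_path = out_dir / "labels.csv"
    with open(notes_path, "w", encoding="utf-8") as fh:
        for case in cases:
            for note in case.notes:
                fh.write(
                    json.dumps(
                        {
                            "case_id": note.case_id,
                            "note_type": note.note_type,
                            "date": note.date,
                            "text": note.text,
                        }
                    )
                    + "\n"
                )
    with open(labels_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "adjudicated_intent", "icd_intent"])
        for case in cases:
            writer.writerow([case.case_id, case.true_intent, case.icd_intent])
    return {"notes": notes_path, "labels": labels_path}


def read_notes_jsonl(path: str | Path) -> dict[str, list[ClinicalNote]]:
    """Read the JSON-lines note format into per-case note lists, preserving
    order. Malformed lines raise with their line number."""
    by_case: dict[str, list[ClinicalNote]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                note = ClinicalNote(
                    case_id=obj["case_id"],
                    note_type=obj.get("note_type", ""),
                    date=obj.get("date", ""),
                    text=obj["text"],
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path} line {lineno}: malformed note record: {exc}")
            by_case.setdefault(note.case_id, []).append(note)
    return by_case
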