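"""Expert rule engine: declarative rules over a case extraction → binary features.

Rules are data, not code: a ruleset file declares each rule's id, kind and a
predicate built from a small clause language (``require_category``,
``require_tag``, ``event_role``, ``event_flag``, ``pair_count``,
``count_explicit`` / ``distinct_explicit_intents``). The engine evaluates
the full ruleset over one :class:`CaseExtraction` and emits an ordered 0/1
feature vector; meta rules (no-explicit-intent, conflicting-intent) see only
the explicit-intent rules' outcomes, never other meta rules, so there are
no cycles by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .extraction import CaseExtraction, count_unique_term_context_pairs

RULE_KINDS = ("explicit_intent", "role", "location", "info_density", "meta")

INTENTS = ("accident", "assault", "legal_intervention", "self_harm", "unknown")


class RuleError(ValueError):
    pass


@dataclass(frozen=True)
class Rule:
    id: str
    kind: str
    predicate: Mapping
    intent: str | None = None  # explicit_intent rules carry their intent

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise RuleError(f"rule {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "explicit_intent" and self.intent not in INTENTS:
            raise RuleError(f"rule {self.id!r}: explicit_intent needs a valid intent")
        object.__setattr__(self, "predicate", dict(self.predicate))


@dataclass
class RuleConfig:
    """Tuned thresholds for the information-density rules."""

    high_info_threshold: int = 5
    low_info_threshold: int = 3

    def __post_init__(self) -> None:
        if self.high_info_threshold < 1 or self.low_info_threshold < 1:
            raise RuleError("info thresholds must be positive")
        if self.low_info_threshold > self.high_info_threshold:
            raise RuleError("low_info_threshold must be <= high_info_threshold")


@dataclass
class RuleFeatureVector:
    case_id: str
    features: dict[str, int] = field(default_factory=dict)

    def as_list(self) -> list[int]:
        return list(self.features.values())


def load_ruleset(path: str | Path) -> list[Rule]:
    """Load rules from JSON: {"rules": [{"id", "kind", "intent"?, "predicate"}]}."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    rules = [
        Rule(r["id"], r["kind"], r.get("predicate", {}), r.get("intent"))
        for r in data["rules"]
    ]
    validate_ruleset(rules)
    return rules


def ruleset_hash(rules: Sequence[Rule]) -> str:
    """Stable digest of the ruleset declaration; stored in model manifests so
    a model refuses feature vectors from a different ruleset."""
    payload = json.dumps(
        [
            {"id": r.id, "kind": r.kind, "intent": r.intent, "predicate": r.predicate}
            for r in rules
        ],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_ruleset(rules: Sequence[Rule]) -> None:
    ids = [r.id for r in rules]
    if len(set(ids)) != len(ids):
        raise RuleError("duplicate rule ids")
    for r in rules:
        op = r.predicate.get("op")
        if r.kind == "meta" and op not in {"count_explicit", "distinct_explicit_intents"}:
            raise RuleError(f"meta rule {r.id!r} must count explicit-intent rules")
        if r.kind != "meta" and op in {"count_explicit", "distinct_explicit_intents"}:
            raise RuleError(f"rule {r.id!r}: only meta rules may reference other rules")


def _mention_ok(m, forbid: Sequence[str]) -> bool:
    return not any(getattr(m, mod) for mod in forbid)


_CMP = {
    "ge": lambda a, b: a >= b,
    "gt": lambda a, b: a > b,
    "le": lambda a, b: a <= b,
    "lt": lambda a, b: a < b,
    "eq": lambda a, b: a == b,
}


#: Shooter phrases that are objects, not people — a "gun discharged" clause
#: must not satisfy a person-shooter requirement.
NONPERSON_SHOOTERS = frozenset(
    {"gun", "guns", "firearm", "weapon", "handgun", "rifle", "pistol",
     "shotgun", "bullet", "it", "round"}
)


def _eval_predicate(
    rule: Rule,
    x: CaseExtraction,
    cfg: RuleConfig,
    explicit_outcomes: Mapping[str, tuple[str, int]],
    police_surfaces: frozenset[str],
) -> int:
    p = rule.predicate
    op = p.get("op")
    if op == "require_category":
        forbid = p.get("forbid_modifiers", ["negated", "historical", "other_subject"])
        cats = p["category"]
        cats = {cats} if isinstance(cats, str) else set(cats)
        return int(
            any(m.term.category in cats and _mention_ok(m, forbid) for m in x.mentions)
        )
    if op == "require_tag":
        forbid = p.get("forbid_modifiers", ["negated", "historical"])
        return int(
            any(
                m.term.category == p["category"]
                and m.term.tags.get(p["tag"]) == p["value"]
                and _mention_ok(m, forbid)
                for m in x.mentions
            )
        )
    if op == "event_role":
        role = p["role"]
        exclude = set(p.get("exclude", ()))
        want_cat = p.get("match_category")
        for ev in x.shooting_events:
            value = getattr(ev, role, None)
            if value is None:
                continue
            words = set(value.lower().split())
            if "self" in exclude and ev.self_directed:
                continue
            if "police" in exclude and words & police_surfaces:
                continue
            if "nonperson" in exclude and role == "shooter":
                content = words - {"the", "a", "an"}
                if content and content <= NONPERSON_SHOOTERS:
                    continue
            if want_cat is not None:
                if want_cat == "police_actor" and not (words & police_surfaces):
                    continue
            return 1
        return 0
    if op == "event_flag":
        return int(any(getattr(ev, p["flag"], False) for ev in x.shooting_events))
    if op == "pair_count":
        scope = p.get("scope", "per_case")
        threshold = p["threshold"]
        if threshold == "high_info_threshold":
            threshold = cfg.high_info_threshold
        elif threshold == "low_info_threshold":
            threshold = cfg.low_info_threshold
        if scope == "per_note_max":
            counts = count_unique_term_context_pairs(x, "per_note")
            value = max(counts, default=0) if counts else 0
        else:
            value = count_unique_term_context_pairs(x, "per_case")
        return int(_CMP[p.get("cmp", "ge")](value, int(threshold)))
    if op == "count_explicit":
        n_true = sum(v for _, v in explicit_outcomes.values())
        return int(_CMP[p.get("cmp", "eq")](n_true, int(p["value"])))
    if op == "distinct_explicit_intents":
        intents = {intent for intent, v in explicit_outcomes.values() if v}
        return int(_CMP[p.get("cmp", "ge")](len(intents), int(p["value"])))
    raise RuleError(f"rule {rule.id!r}: unknown predicate op {op!r}")


def evaluate_rules(
    x: CaseExtraction,
    ruleset: Sequence[Rule],
    cfg: RuleConfig | None = None,
    police_surfaces: Sequence[str] = ("police", "officer", "officers", "swat", "cop", "cops"),
) -> RuleFeatureVector:
    """Evaluate every rule; explicit-intent rules first so meta rules can
    count them. Pure function of the extraction and config."""
    cfg = cfg or RuleConfig()
    validate_ruleset(ruleset)
    police = frozenset(s.lower() for s in police_surfaces)

    explicit_outcomes: dict[str, tuple[str, int]] = {}
    results: dict[str, int] = {}
    for rule in ruleset:
        if rule.kind == "meta":
            continue
        v = _eval_predicate(rule, x, cfg, explicit_outcomes, police)
        results[rule.id] = v
        if rule.kind == "explicit_intent":
            explicit_outcomes[rule.id] = (rule.intent, v)
    for rule in ruleset:
        if rule.kind == "meta":
            results[rule.id] = _eval_predicate(rule, x, cfg, explicit_outcomes, police)

    return RuleFeatureVector(
        case_id=x.case_id, features={r.id: results[r.id] for r in ruleset}
    )


def rule_high_info_note(x: CaseExtraction, cfg: RuleConfig) -> bool:
    """True iff the best note reaches the high-information threshold."""
    counts = count_unique_term_context_pairs(x, "per_note")
    return bool(counts) and max(counts) >= cfg.high_info_threshold


def rule_low_info_case(x: CaseExtraction, cfg: RuleConfig) -> bool:
    """True iff the whole case falls below the low-information threshold."""
    return count_unique_term_context_pairs(x, "per_case") < cfg.low_info_threshold


def rule_no_explicit_intent(explicit_flags: Mapping[str, int]) -> bool:
    return sum(explicit_flags.values()) == 0


def rule_conflicting_intent(explicit_flags_by_intent: Mapping[str, int]) -> bool:
    """Conflict = distinct intents asserted, not repeated cues of one intent."""
    return sum(1 for v in explicit_flags_by_intent.values() if v) >= 2


def default_ruleset_path() -> Path:
    return Path(__file__).parent / "data" / "ruleset.json"


def tune_info_threshold(
    cases: Sequence[CaseExtraction],
    labels: Sequence[str],
    ruleset: Sequence[Rule],
    grid: Sequence[int] = tuple(range(1, 16)),
    classifier_factory=None,
    seed: int = 0,
    low_info_default: int = 3,
    train_cases: Sequence[CaseExtraction] | None = None,
    train_labels: Sequence[str] | None = None,
) -> RuleConfig:
    """Pick the info-density threshold maximizing unknown-intent F-score.

    For each grid value t the high-info threshold is set to t (low-info to
    min(t, *low_info_default*)), the rule features are recomputed, the
    end-to-end classifier is fitted on *train_cases* (the tuning cases
    themselves when no separate training partition is given) and the
    unknown-class F is measured on the tuning cases. Fitting on a separate
    partition matters: fitting and scoring on the same cases lets every
    threshold reach the same overfit F-score, collapsing the choice to the
    tie-break. Ties resolve to the smallest threshold.
    """
    from .classifier import IntentClassifier
    from .evaluation import confusion_matrix, per_class_metrics

    if "unknown" not in set(labels):
        raise ValueError("tuning data contains no unknown-intent cases")
    if classifier_factory is None:
        classifier_factory = lambda: IntentClassifier(random_state=seed)  # noqa: E731
    if train_cases is None:
        train_cases, train_labels = cases, labels

    import pandas as pd

    best: tuple[float, int] | None = None
    for t in grid:
        cfg = RuleConfig(high_info_threshold=t, low_info_threshold=min(t, low_info_default))
        X_train = pd.DataFrame(
            [evaluate_rules(x, ruleset, cfg).features for x in train_cases]
        )
        X_tune = pd.DataFrame(
            [evaluate_rules(x, ruleset, cfg).features for x in cases]
        )
        clf = classifier_factory()
        clf.fit(X_train, list(train_labels))
        pred = clf.predict(X_tune)
        m = per_class_metrics(confusion_matrix(list(pred), list(labels)))
        f_unknown = float(m.loc["unknown", "f_score"])
        if best is None or f_unknown > best[0] + 1e-12:
            best = (f_unknown, t)
    assert best is not None
    return RuleConfig(
        high_info_threshold=best[1], low_info_threshold=min(best[1], low_info_default)
    )
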