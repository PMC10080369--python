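"""End-to-end orchestration: notes → extraction → rules → classifier → report.

This is the glue the CLI and the benchmark scripts use. It owns default
resources (starter lexicon, context triggers, default ruleset, pattern
parser) and the standard experiment: split cases, tune the information
threshold, train gradient-boosted stumps, evaluate, and compare against the
ICD-coded arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import IntentClassifier, RuleFeaturizer
from .dependency import PatternParser
from .evaluation import (
    CLASS_ORDER,
    confusion_matrix,
    compare_to_icd,
    per_class_metrics,
    roc_pr_curves,
    split_cases,
    unweighted_average_f,
)
from .extraction import CaseExtraction, ContextConfig, aggregate_case
from .lexicon import Lexicon, load_lexicon
from .rules import Rule, RuleConfig, load_ruleset, tune_info_threshold

_DATA = Path(__file__).parent / "data"


def default_lexicon() -> Lexicon:
    return load_lexicon(_DATA / "lexicon.tsv")


def default_context() -> ContextConfig:
    return ContextConfig.from_file(_DATA / "context_triggers.tsv")


def default_rules() -> list[Rule]:
    return load_ruleset(_DATA / "ruleset.json")


def default_parser() -> PatternParser:
    verbs = [t.text for t in default_lexicon().terms_of_category("shooting_verb")]
    return PatternParser(verbs)


def extract_cases(
    notes_by_case: Mapping[str, Sequence],
    lexicon: Lexicon | None = None,
    context: ContextConfig | None = None,
    parser=None,
) -> dict[str, CaseExtraction]:
    lexicon = lexicon or default_lexicon()
    context = context or default_context()
    parser = parser or PatternParser(
        [t.text for t in lexicon.terms_of_category("shooting_verb")]
    )
    return {
        cid: aggregate_case(list(notes), lexicon, context, parser=parser)
        for cid, notes in notes_by_case.items()
    }


@dataclass
class ExperimentResult:
    """Everything the standard synthetic benchmark produces."""

    rule_config: RuleConfig
    model: IntentClassifier
    featurizer: RuleFeaturizer
    test_ids: list[str]
    predictions: pd.Series
    probabilities: pd.DataFrame
    test_metrics: pd.DataFrame
    test_average_f: float
    majority_baseline_f: float
    confusion: object
    icd_comparison: pd.DataFrame | None = None
    curves: pd.DataFrame | None = None
    feature_importances: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def majority_baseline_average_f(labels: Sequence[str]) -> float:
    """Unweighted average F of always predicting the most common class."""
    values, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    majority = values[int(np.argmax(counts))]
    pred = [majority] * len(labels)
    return unweighted_average_f(per_class_metrics(confusion_matrix(pred, list(labels))))


def run_experiment(
    extractions: Mapping[str, CaseExtraction],
    labels: Mapping[str, str],
    icd_labels: Mapping[str, str] | None = None,
    fractions=(0.6, 0.2, 0.2),
    seed: int = 0,
    algorithm: str = "gbm",
    hyperparameters: Mapping | None = None,
    ruleset: Sequence[Rule] | None = None,
    tune_grid: Sequence[int] = tuple(range(1, 16)),
) -> ExperimentResult:
    """The standard experiment: split, tune the info threshold on the tuning
    partition, train on the training partition, evaluate on the test
    partition (and against the ICD arm if ICD labels are given)."""
    ruleset = list(ruleset) if ruleset is not None else default_rules()
    case_ids = sorted(extractions)
    split = split_cases(case_ids, fractions, seed=seed)
    parts = {p: split.ids(p) for p in ("train", "tune", "test")}
    if not parts["tune"]:  # 2-way splits tune on the training partition
        parts["tune"] = parts["train"]

    cfg = tune_info_threshold(
        [extractions[c] for c in parts["tune"]],
        [labels[c] for c in parts["tune"]],
        ruleset,
        grid=tune_grid,
        seed=seed,
        train_cases=[extractions[c] for c in parts["train"]],
        train_labels=[labels[c] for c in parts["train"]],
    )
    featurizer = RuleFeaturizer(ruleset=ruleset, rule_config=cfg).fit()

    X = {
        p: featurizer.transform([extractions[c] for c in ids])
        for p, ids in parts.items()
    }
    y = {p: [labels[c] for c in ids] for p, ids in parts.items()}

    model = IntentClassifier(
        algorithm=algorithm, hyperparameters=hyperparameters, random_state=seed
    ).fit(X["train"], y["train"])

    pred = model.predict(X["test"])
    proba = pd.DataFrame(
        model.predict_proba(X["test"]),
        columns=[str(c) for c in model.classes_],
        index=parts["test"],
    )
    for c in CLASS_ORDER:
        if c not in proba.columns:
            proba[c] = 0.0
    proba = proba[list(CLASS_ORDER)]

    cm = confusion_matrix(list(pred), y["test"])
    metrics = per_class_metrics(cm)
    result = ExperimentResult(
        rule_config=cfg,
        model=model,
        featurizer=featurizer,
        test_ids=parts["test"],
        predictions=pd.Series(pred, index=parts["test"]),
        probabilities=proba,
        test_metrics=metrics,
        test_average_f=unweighted_average_f(metrics),
        majority_baseline_f=majority_baseline_average_f(y["test"]),
        confusion=cm,
        curves=roc_pr_curves(proba, y["test"]),
        feature_importances=model.feature_importances(),
    )
    if icd_labels is not None:
        result.icd_comparison = compare_to_icd(
            [icd_labels.get(c) for c in parts["test"]],
            list(pred),
            y["test"],
        )
    return result


def run_synthetic_benchmark(
    n: int = 1000,
    seed: int = 0,
    profile=None,
    fractions=(0.6, 0.2, 0.2),
    algorithm: str = "gbm",
) -> ExperimentResult:
    """Generate a synthetic corpus and run the standard experiment on it."""
    from .synthetic import generate_corpus, mds_profile

    profile = profile or mds_profile()
    cases = generate_corpus(n, profile, seed=seed)
    extractions = extract_cases({c.case_id: c.notes for c in cases})
    labels = {c.case_id: c.true_intent for c in cases}
    icd = {c.case_id: c.icd_intent for c in cases}
    result = run_experiment(
        extractions, labels, icd_labels=icd, fractions=fractions,
        seed=seed, algorithm=algorithm,
    )
    result.extras["cases"] = cases
    return result
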