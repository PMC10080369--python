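"""Intent classifiers over binary rule features, sklearn-estimator shaped.

:class:`IntentClassifier` wraps the shallow ensemble used in production —
gradient-boosted stumps (depth 1, learning rate 0.1, 300 trees) — plus the
comparison algorithms (random forest, maximum entropy, SVM, AdaBoost, kNN),
adding the deterministic tie-break the pipeline specifies: exact probability
ties resolve to the most prevalent training class, then class order.
:class:`RuleFeaturizer` turns per-case note collections into the binary rule
feature matrix, so the two compose into a standard sklearn ``Pipeline``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .evaluation import CLASS_ORDER

MODEL_FORMAT_VERSION = 1

#: The production defaults: shallow boosting over binary rule features.
GBM_DEFAULTS = {"max_depth": 1, "learning_rate": 0.1, "n_estimators": 300}

ALGORITHMS = ("gbm", "random_forest", "maxent", "svm", "adaboost", "knn")


def _base_estimator(algorithm: str, hyperparameters: Mapping, seed):
    hp = dict(hyperparameters)
    if algorithm == "gbm":
        return GradientBoostingClassifier(**{**GBM_DEFAULTS, **hp}, random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(**hp, random_state=seed)
    if algorithm == "maxent":
        return LogisticRegression(max_iter=1000, **hp)
    if algorithm == "svm":
        return SVC(probability=True, **hp, random_state=seed)
    if algorithm == "adaboost":
        return AdaBoostClassifier(**hp, random_state=seed)
    if algorithm == "knn":
        return KNeighborsClassifier(**hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class IntentClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass intent classifier over binary rule features.

    Parameters
    ----------
    algorithm:
        One of ``gbm`` (default), ``random_forest``, ``maxent``, ``svm``,
        ``adaboost``, ``knn``.
    hyperparameters:
        Overrides passed to the underlying scikit-learn estimator. For gbm
        the defaults are depth 1, learning rate 0.1, 300 trees.
    random_state:
        Seed for every stochastic component; fixed seed ⇒ identical model.
    """

    def __init__(
        self,
        algorithm: str = "gbm",
        hyperparameters: Mapping | None = None,
        random_state: int | None = 0,
    ):
        self.algorithm = algorithm
        self.hyperparameters = hyperparameters
        self.random_state = random_state

    def fit(self, X, y):
        X, feature_names = _as_matrix(X)
        y = np.asarray(y, dtype=object)
        if X.shape[0] != len(y):
            raise ValueError("feature matrix and labels differ in length")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        self.feature_names_ = feature_names
        self.estimator_ = _base_estimator(
            self.algorithm, self.hyperparameters or {}, self.random_state
        )
        self.estimator_.fit(X, y)
        self.classes_ = self.estimator_.classes_
        prevalence = {c: n for c, n in zip(classes, counts)}
        self.class_prevalence_ = np.array(
            [prevalence.get(c, 0) for c in self.classes_], dtype=int
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X, names = _as_matrix(X)
        self._check_features(names, X.shape[1])
        proba = self.estimator_.predict_proba(X)
        return proba / proba.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Argmax of the class probabilities; exact ties go to the class with
        the higher training prevalence, then to class order."""
        proba = self.predict_proba(X)
        order = np.lexsort(
            (np.arange(len(self.classes_)), -self.class_prevalence_)
        )  # prevalence desc, then declaration order
        out = []
        for row in proba:
            # argmax scanned in tie-break order: first hit wins exact ties
            best = order[int(np.argmax(row[order]))]
            out.append(self.classes_[best])
        return np.asarray(out, dtype=object)

    def feature_importances(
        self, X=None, y=None, n_repeats: int = 10
    ) -> pd.DataFrame:
        """Ranked feature importances.

        Tree ensembles expose impurity importances (non-negative, summing to
        1). Other algorithms fall back to permutation importance, which needs
        the data (``X``, ``y``) and uses the estimator's seed.
        """
        check_is_fitted(self, "estimator_")
        if hasattr(self.estimator_, "feature_importances_"):
            imp = np.asarray(self.estimator_.feature_importances_, dtype=float)
        else:
            from sklearn.inspection import permutation_importance

            if X is None or y is None:
                raise ValueError(
                    f"{self.algorithm} needs data for permutation importance"
                )
            Xm, names = _as_matrix(X)
            self._check_features(names, Xm.shape[1])
            res = permutation_importance(
                self.estimator_, Xm, np.asarray(y, dtype=object),
                n_repeats=n_repeats, random_state=self.random_state,
            )
            imp = np.maximum(res.importances_mean, 0.0)
        df = pd.DataFrame(
            {"feature": self.feature_names_ or range(len(imp)), "importance": imp}
        )
        return df.sort_values("importance", ascending=False, ignore_index=True)

    def _check_features(self, names, n_cols: int) -> None:
        if self.feature_names_ and names and list(names) != list(self.feature_names_):
            raise ValueError(
                "feature names do not match the model's training features"
            )
        if n_cols != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {n_cols}"
            )


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


# ---------------------------------------------------------------------------
# Featurizer: cases -> binary rule-feature matrix


class RuleFeaturizer(TransformerMixin, BaseEstimator):
    """Transform per-case extractions (or raw note collections) into the
    binary rule-feature matrix.

    Accepts either ready :class:`~firearm_intent.extraction.CaseExtraction`
    objects or lists of :class:`~firearm_intent.extraction.ClinicalNote`
    (then *lexicon*, *context* and *parser* must be set).
    """

    def __init__(
        self,
        ruleset=None,
        rule_config=None,
        lexicon=None,
        context=None,
        parser=None,
    ):
        self.ruleset = ruleset
        self.rule_config = rule_config
        self.lexicon = lexicon
        self.context = context
        self.parser = parser

    def fit(self, X=None, y=None):
        from .rules import load_ruleset, default_ruleset_path, RuleConfig, ruleset_hash

        self.ruleset_ = (
            self.ruleset
            if self.ruleset is not None
            else load_ruleset(default_ruleset_path())
        )
        self.rule_config_ = self.rule_config or RuleConfig()
        self.feature_names_ = [r.id for r in self.ruleset_]
        self.ruleset_hash_ = ruleset_hash(self.ruleset_)
        return self

    def transform(self, X) -> pd.DataFrame:
        from .extraction import CaseExtraction, aggregate_case
        from .rules import evaluate_rules

        check_is_fitted(self, "ruleset_")
        rows, ids = [], []
        for item in X:
            if isinstance(item, CaseExtraction):
                extraction = item
            else:
                extraction = aggregate_case(
                    list(item), self.lexicon, self.context, parser=self.parser
                )
            fv = evaluate_rules(extraction, self.ruleset_, self.rule_config_)
            rows.append(fv.features)
            ids.append(extraction.case_id)
        return pd.DataFrame(rows, index=ids, columns=self.feature_names_, dtype=int)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "ruleset_")
        return np.asarray(self.feature_names_, dtype=object)


# ---------------------------------------------------------------------------
# Persistence


def save_model(
    model: IntentClassifier, path: str | Path, ruleset_hash: str | None = None
) -> None:
    """Persist the fitted model with a JSON manifest (algorithm, features,
    class order, ruleset hash, seed) so loads can refuse incompatible data."""
    check_is_fitted(model, "estimator_")
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "algorithm": model.algorithm,
        "hyperparameters": dict(model.hyperparameters or {}),
        "feature_names": list(model.feature_names_ or []),
        "class_order": [str(c) for c in model.classes_],
        "ruleset_hash": ruleset_hash,
        "seed": model.random_state,
    }
    joblib.dump({"manifest": json.dumps(manifest), "model": model}, path)


def load_model(
    path: str | Path,
    expected_ruleset_hash: str | None = None,
    expected_features: Sequence[str] | None = None,
) -> IntentClassifier:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = joblib.load(path)
    manifest = json.loads(payload["manifest"])
    if manifest.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file format {manifest.get('format_version')} incompatible "
            f"with code format {MODEL_FORMAT_VERSION}"
        )
    if (
        expected_ruleset_hash is not None
        and manifest.get("ruleset_hash") is not None
        and manifest["ruleset_hash"] != expected_ruleset_hash
    ):
        raise ValueError("model was trained under a different ruleset")
    if expected_features is not None and list(expected_features) != manifest[
        "feature_names"
    ]:
        raise ValueError("model feature names do not match the requested ruleset")
    return payload["model"]


def recalibrate(
    model_spec: IntentClassifier | Mapping,
    X,
    y,
    seed: int | None = None,
) -> IntentClassifier:
    """Retrain the same specification (algorithm + hyperparameters) on local
    site data; no fitted state carries over."""
    if isinstance(model_spec, IntentClassifier):
        fresh = clone(IntentClassifier(
            algorithm=model_spec.algorithm,
            hyperparameters=model_spec.hyperparameters,
            random_state=model_spec.random_state if seed is None else seed,
        ))
    else:
        fresh = IntentClassifier(
            algorithm=model_spec.get("algorithm", "gbm"),
            hyperparameters=model_spec.get("hyperparameters"),
            random_state=seed if seed is not None else model_spec.get("seed", 0),
        )
    if len(np.asarray(y)) == 0:
        raise ValueError("local training data is empty")
    return fresh.fit(X, y)


def train(
    features, labels, algorithm: str = "gbm", hyperparameters=None, seed: int = 0
) -> IntentClassifier:
    """Functional wrapper over :class:`IntentClassifier`."""
    return IntentClassifier(algorithm, hyperparameters, random_state=seed).fit(
        features, labels
    )


def compare_algorithms(
    X_train,
    y_train,
    X_tune,
    y_tune,
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
) -> pd.DataFrame:
    """Train each algorithm on the same split and report unweighted average
    F, macro AUROC and macro AUPRC on the tuning set, plus the
    hyperparameters actually used."""
    from .evaluation import (
        confusion_matrix,
        per_class_metrics,
        roc_pr_curves,
        unweighted_average_f,
    )

    rows = []
    for algo in algorithms:
        clf = IntentClassifier(algorithm=algo, random_state=seed).fit(X_train, y_train)
        pred = clf.predict(X_tune)
        metrics = per_class_metrics(confusion_matrix(list(pred), list(y_tune)))
        avg_f = unweighted_average_f(metrics)
        proba = pd.DataFrame(clf.predict_proba(X_tune), columns=list(clf.classes_))
        for c in CLASS_ORDER:
            if c not in proba.columns:
                proba[c] = 0.0
        curves = roc_pr_curves(proba[list(CLASS_ORDER)], list(y_tune))
        rows.append(
            {
                "algorithm": algo,
                "unweighted_average_f": avg_f,
                "auroc": float(np.nanmean(curves["auroc"])),
                "auprc": float(np.nanmean(curves["auprc"])),
                "hyperparameters": json.dumps(
                    clf.estimator_.get_params(), default=str, sort_keys=True
                ),
            }
        )
    return pd.DataFrame(rows)
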