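"""Confusion matrices, per-class metrics, splits, and model-vs-ICD reports.

Conventions: confusion-matrix rows are the predicted intent and columns the
adjudicated (gold) intent, class order fixed as (accident, assault,
legal_intervention, self_harm, unknown). Per-class metrics are computed in
exact rational arithmetic from the counts, and rounded half-up to 2 decimals
only at report time. The 0/0 convention is 0 for precision/recall/F and 1
for specificity — needed for classes with tiny counts (legal intervention).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CLASS_ORDER = ("accident", "assault", "legal_intervention", "self_harm", "unknown")


def round_half_up(x: float | Fraction, digits: int = 2) -> float:
    """Half-up rounding (as printed in clinical tables), not banker's."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-digits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows predicted, cols adjudicated
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}x{k} counts, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:  # predicted-label counts
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:  # adjudicated counts
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if tuple(df.index) != CLASS_ORDER or tuple(df.columns) != CLASS_ORDER:
            raise ValueError(f"{path}: rows/columns must be {CLASS_ORDER}")
        return cls(df.to_numpy())


def confusion_matrix(
    predicted: Sequence[str], adjudicated: Sequence[str]
) -> ConfusionMatrix:
    if len(predicted) != len(adjudicated):
        raise ValueError("label vectors differ in length")
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((5, 5), dtype=int)
    for p, a in zip(predicted, adjudicated):
        if p not in idx or a not in idx:
            raise ValueError(f"label outside class set: {p!r}/{a!r}")
        counts[idx[p], idx[a]] += 1
    return ConfusionMatrix(counts)


def _safe_div(num: int, den: int, zero: Fraction = Fraction(0)) -> Fraction:
    return Fraction(num, den) if den else zero


def per_class_metrics(m: ConfusionMatrix, exact: bool = False) -> pd.DataFrame:
    """Specificity, precision, recall and F per class from the matrix alone.

    With ``exact=True`` cells hold :class:`fractions.Fraction`; otherwise
    floats (still computed from the exact fractions).
    """
    rows = {}
    total = m.total
    row_s, col_s = m.row_sums(), m.col_sums()
    for i, c in enumerate(m.classes):
        tp = int(m.counts[i, i])
        fp = int(row_s[i]) - tp
        fn = int(col_s[i]) - tp
        tn = total - tp - fp - fn
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        specificity = _safe_div(tn, tn + fp, zero=Fraction(1))
        f = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else Fraction(0)
        )
        rows[c] = {
            "specificity": specificity,
            "precision": precision,
            "recall": recall,
            "f_score": f,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[list(m.classes)]
    if not exact:
        df = df.map(float)
    return df


def unweighted_average_f(metrics: pd.DataFrame) -> float:
    """Arithmetic mean of the per-class F-scores (macro-F over the 5 intents)."""
    vals = [Fraction(v) if not isinstance(v, Fraction) else v for v in metrics["f_score"]]
    return float(sum(vals) / len(vals))


def rounded_report(m: ConfusionMatrix, digits: int = 2) -> pd.DataFrame:
    """Per-class metrics plus the macro-F row, rounded half-up for reporting."""
    exact = per_class_metrics(m, exact=True)
    out = exact.map(lambda v: round_half_up(v, digits))
    out.loc["average", "f_score"] = round_half_up(
        sum(exact["f_score"]) / len(exact), digits
    )
    return out


def roc_pr_curves(
    probabilities: np.ndarray | pd.DataFrame,
    adjudicated: Sequence[str],
    classes: Sequence[str] = CLASS_ORDER,
) -> pd.DataFrame:
    """One-vs-rest AUROC (trapezoid) and AUPRC (step-wise) per class.

    A class absent from the truth labels gets NaN (undefined), not 0.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    if isinstance(probabilities, pd.DataFrame):
        probabilities = probabilities[list(classes)].to_numpy()
    probabilities = np.asarray(probabilities, dtype=float)
    y = np.asarray(adjudicated)
    out = {}
    for j, c in enumerate(classes):
        truth = (y == c).astype(int)
        if truth.sum() == 0 or truth.sum() == len(truth):
            out[c] = {"auroc": float("nan"), "auprc": float("nan")}
            continue
        out[c] = {
            "auroc": float(roc_auc_score(truth, probabilities[:, j])),
            "auprc": float(average_precision_score(truth, probabilities[:, j])),
        }
    return pd.DataFrame.from_dict(out, orient="index").loc[list(classes)]


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # case_id -> train|tune|test
    fractions: tuple[float, ...]
    seed: int

    def ids(self, part: str) -> list[str]:
        return [cid for cid, p in self.assignment.items() if p == part]


def split_cases(
    case_ids: Sequence[str],
    fractions: Mapping[str, float] | Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    parts: Sequence[str] = ("train", "tune", "test"),
) -> SplitAssignment:
    """Uniform random permutation under *seed*, then contiguous allocation.

    Realized sizes use largest-remainder apportionment, so each part is
    within one case of its target fraction.
    """
    if isinstance(fractions, Mapping):
        parts = tuple(fractions.keys())
        fracs = tuple(fractions.values())
    else:
        fracs = tuple(fractions)
        parts = tuple(parts)[: len(fracs)]
    if not case_ids:
        raise ValueError("no cases to split")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(case_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    raw = [f * n for f in fracs]
    sizes = [int(r) for r in raw]
    remainders = sorted(
        range(len(fracs)), key=lambda i: (raw[i] - sizes[i], -i), reverse=True
    )
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1
    assignment: dict[str, str] = {}
    pos = 0
    for part, size in zip(parts, sizes):
        for k in order[pos : pos + size]:
            assignment[case_ids[k]] = part
        pos += size
    return SplitAssignment(assignment, fracs, seed)


def compare_to_icd(
    icd_labels: Sequence[str | None],
    model_labels: Sequence[str],
    adjudicated: Sequence[str],
) -> pd.DataFrame:
    """Side-by-side per-class metrics: ICD-vs-adjudicated and model-vs-
    adjudicated, restricted to the cases that have an ICD label (cases
    without hospital-assigned codes are excluded from both arms)."""
    if not (len(icd_labels) == len(model_labels) == len(adjudicated)):
        raise ValueError("label vectors must align")
    keep = [i for i, v in enumerate(icd_labels) if v is not None and v == v and v != ""]
    icd = [icd_labels[i] for i in keep]
    mod = [model_labels[i] for i in keep]
    adj = [adjudicated[i] for i in keep]
    frames = []
    for arm, labels in (("icd", icd), ("model", mod)):
        df = per_class_metrics(confusion_matrix(labels, adj))
        df.insert(0, "arm", arm)
        frames.append(df.reset_index(names="intent"))
    return pd.concat(frames, ignore_index=True)
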