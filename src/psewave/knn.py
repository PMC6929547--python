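"""K-nearest-neighbor classification, jackknife validation, and the
per-class performance measures.

The classifier uses Euclidean distance.  Ties are resolved
deterministically: equal distances are broken by lower training-row index;
a tied majority vote among the k nearest is broken by the class of the
nearest neighbor belonging to one of the tied classes.

Evaluation is one-vs-rest per class: from the jackknife (leave-one-out)
prediction list we tally TP/FP/TN/FN for each class and report

    Sens = TP/(TP+FN)      Spec = TN/(FP+TN)
    MCC  = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus the multiclass overall accuracy OA (fraction of samples predicted
correctly).  Any metric with a zero denominator is reported as 0.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Label = Hashable


def knn_predict(train: np.ndarray, train_labels: Sequence[Label],
                query: np.ndarray, k: int) -> Label:
    """Majority class among the k nearest training rows (Euclidean)."""
    train = np.asarray(train, dtype=float)
    query = np.asarray(query, dtype=float).ravel()
    n = train.shape[0]
    if len(train_labels) != n:
        raise ValueError("train rows and labels differ in length")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and the number of training rows ({n})")
    if query.size != train.shape[1]:
        raise ValueError(f"query dimension {query.size} does not match training dimension {train.shape[1]}")
    dists = np.sqrt(((train - query) ** 2).sum(axis=1))
    order = np.argsort(dists, kind="stable")  # equal distances -> lower index first
    top = order[:k]
    votes = Counter(train_labels[i] for i in top)
    best = max(votes.values())
    tied = {cls for cls, c in votes.items() if c == best}
    if len(tied) == 1:
        return tied.pop()
    for i in top:  # nearest neighbor among the tied classes
        if train_labels[i] in tied:
            return train_labels[i]
    raise AssertionError("unreachable")  # pragma: no cover


def jackknife(matrix: np.ndarray, labels: Sequence[Label], k: int = 1) -> list[Label]:
    """Leave-one-out predictions: sample i is classified by all others."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("jackknife needs at least 2 samples")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the jackknife training size {n - 1}")
    labels = list(labels)
    preds: list[Label] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        rest_labels = labels[:i] + labels[i + 1:]
        preds.append(knn_predict(X[mask], rest_labels, X[i], k))
        mask[i] = True
    return preds


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_for_class(predictions: Sequence[Label], labels: Sequence[Label],
                        cls: Label) -> ConfusionCounts:
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, labels):
        if t == cls:
            if p == cls:
                tp += 1
            else:
                fn += 1
        else:
            if p == cls:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("zero denominator in %s; reporting 0", what)
        return 0.0
    return num / den


def sens(c: ConfusionCounts) -> float:
    """Sensitivity TP/(TP+FN); 0 if the class never occurs."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def spec(c: ConfusionCounts) -> float:
    """Specificity TN/(FP+TN); 0 if everything is the class."""
    return _ratio(c.tn, c.fp + c.tn, "specificity")


def oa_binary(c: ConfusionCounts) -> float:
    """Binary (one-vs-rest) accuracy (TP+TN)/n."""
    return _ratio(c.tp + c.tn, c.n, "binary accuracy")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 on a degenerate denominator."""
    den = float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        logger.debug("zero denominator in MCC; reporting 0")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(den)


def overall_accuracy(predictions: Sequence[Label], labels: Sequence[Label]) -> float:
    """Multiclass fraction of samples whose prediction equals the truth."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    if not labels:
        raise ValueError("empty prediction list")
    return sum(p == t for p, t in zip(predictions, labels)) / len(labels)


@dataclass(frozen=True)
class ClassMetrics:
    counts: ConfusionCounts
    sens: float
    spec: float
    mcc: float
    oa_binary: float


@dataclass
class EvaluationReport:
    """Per-class one-vs-rest metrics plus the multiclass overall accuracy."""

    per_class: dict[str, ClassMetrics]
    oa: float
    predictions: list[tuple[str, str, str]] = field(default_factory=list)  # (id, true, predicted)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                cls: {
                    "tp": m.counts.tp, "fp": m.counts.fp,
                    "tn": m.counts.tn, "fn": m.counts.fn,
                    "sens": m.sens, "spec": m.spec, "mcc": m.mcc,
                }
                for cls, m in self.per_class.items()
            },
            "oa": self.oa,
            "predictions": [list(p) for p in self.predictions],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        rows = [
            {"class": cls, "n": m.counts.tp + m.counts.fn,
             "Sens(%)": 100 * m.sens, "Spec(%)": 100 * m.spec, "MCC": m.mcc}
            for cls, m in self.per_class.items()
        ]
        table = pd.DataFrame(rows).to_string(index=False, float_format=lambda x: f"{x:.3f}")
        return f"{table}\nOA(%): {100 * self.oa:.2f}  (n={len(self.predictions) or sum(r['n'] for r in rows)})"


def build_report(predictions: Sequence[Label], labels: Sequence[Label],
                 ids: Sequence[str] | None = None) -> EvaluationReport:
    """Tally one-vs-rest metrics for every class present in the truth."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    classes = sorted({str(getattr(t, "value", t)) for t in labels})
    key = lambda x: str(getattr(x, "value", x))
    pred_keys = [key(p) for p in predictions]
    true_keys = [key(t) for t in labels]
    per_class = {}
    for cls in classes:
        c = confusion_for_class(pred_keys, true_keys, cls)
        per_class[cls] = ClassMetrics(counts=c, sens=sens(c), spec=spec(c),
                                      mcc=mcc(c), oa_binary=oa_binary(c))
    if ids is None:
        ids = [str(i) for i in range(len(labels))]
    return EvaluationReport(
        per_class=per_class,
        oa=overall_accuracy(pred_keys, true_keys),
        predictions=list(zip([str(i) for i in ids], true_keys, pred_keys)),
    )
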