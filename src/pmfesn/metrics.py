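"""Imbalance-insensitive evaluation metrics for ordinal outcome classification.

Class imbalance makes plain accuracy and plain MAE misleading: a classifier
that always predicts the majority mRS grade scores well on both. Every metric
here therefore weights classes equally (macro averaging) or corrects for
marginals (multiclass Matthews correlation):

* ``macro_mae`` — mean absolute label deviation computed per class, then
  averaged over classes with equal weight; range [0, M-1].
* ``per_class_pr`` / ``macro_prf`` — per-class precision/recall from a
  confusion matrix and their unweighted means; the macro F1 is the harmonic
  mean of the macro precision and macro recall.
* ``mcc_multiclass`` — Gorodkin's multiclass Matthews correlation
  coefficient, computed from the confusion matrix trace and marginals.
* ``per_class_auc`` — one-vs-rest rank AUC per class (ties count 1/2).

Per-class "accuracy" of a multiclass confusion matrix is the within-class hit
rate, i.e. identical to per-class recall; reports expose it under both names.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "FoldRecord",
    "confusion_from_labels",
    "macro_mae",
    "per_class_pr",
    "macro_prf",
    "mcc_multiclass",
    "per_class_auc",
    "build_report",
]


def _as_confusion(cm: "ConfusionMatrix | np.ndarray") -> np.ndarray:
    arr = cm.table if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"confusion matrix must be square 2-D, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    return arr


@dataclass(frozen=True)
class ConfusionMatrix:
    """M x M contingency table; rows are true classes, columns predicted."""

    table: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=int)
        if arr.size == 0:
            raise ValueError("confusion matrix must be non-empty")
        _as_confusion(arr)
        object.__setattr__(self, "table", arr)

    @property
    def n_classes(self) -> int:
        return self.table.shape[0]

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConfusionMatrix) and np.array_equal(self.table, other.table)


def confusion_from_labels(true: Sequence[int], pred: Sequence[int], n_classes: int) -> ConfusionMatrix:
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("true and pred must have the same length")
    table = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(table, (true, pred), 1)
    return ConfusionMatrix(table)


def macro_mae(true: Sequence[int], pred: Sequence[int], n_classes: int) -> float:
    """Macro-averaged mean absolute error over ordinal labels 0..M-1.

    The absolute label deviation |y - y_hat| is averaged within each true
    class, and those per-class means are averaged with equal weight, so a
    3-case class counts as much as an 18-case class. Classes absent from
    ``true`` are dropped from the average (their within-class mean is
    undefined) with a warning.
    """
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if true.shape != pred.shape:
        raise ValueError("true and pred must have the same length")
    per_class = []
    absent = []
    for m in range(n_classes):
        mask = true == m
        if not mask.any():
            absent.append(m)
            continue
        per_class.append(float(np.abs(true[mask] - pred[mask]).mean()))
    if absent:
        warnings.warn(
            f"classes {absent} absent from the truth vector; excluded from macro MAE",
            stacklevel=2,
        )
    if not per_class:
        raise ValueError("no class present in the truth vector")
    return float(np.mean(per_class))


def per_class_pr(confusion: "ConfusionMatrix | np.ndarray") -> tuple[np.ndarray, np.ndarray]:
    """Per-class precision (diag/column sum) and recall (diag/row sum).

    A zero denominator (class never predicted, resp. never true) yields 0,
    matching the zeros reported for never-predicted classes.
    """
    cm = _as_confusion(confusion).astype(float)
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
    return precision, recall


def macro_prf(precision: Sequence[float], recall: Sequence[float]) -> tuple[float, float, float]:
    """Macro precision, macro recall, and their harmonic-mean F1.

    F1 is the harmonic mean *of the two macro averages* (not the mean of
    per-class F1 scores); 0 when both macros are 0.
    """
    p = float(np.mean(np.asarray(precision, dtype=float)))
    r = float(np.mean(np.asarray(recall, dtype=float)))
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


def mcc_multiclass(confusion: "ConfusionMatrix | np.ndarray") -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin).

    With c the trace, s the total count, t_k the row sums and p_k the column
    sums:  MCC = (c*s - sum p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2)).
    Returns 0 when either radicand vanishes (a degenerate marginal).
    """
    cm = _as_confusion(confusion).astype(float)
    s = cm.sum()
    if s <= 0:
        raise ValueError("confusion matrix total must be positive")
    c = np.trace(cm)
    t = cm.sum(axis=1)
    p = cm.sum(axis=0)
    cov = c * s - p @ t
    var_t = s * s - t @ t
    var_p = s * s - p @ p
    if var_t <= 0 or var_p <= 0:
        return 0.0
    return float(cov / np.sqrt(var_t * var_p))


def per_class_auc(scores: np.ndarray, true: Sequence[int]) -> list[Optional[float]]:
    """One-vs-rest rank AUC per class from an (N, M) score matrix.

    ``scores[i, m]`` is the classifier's score for case i belonging to class
    m (here: its maximum similarity to class-m reference samples). A class
    without both a positive and a negative case has an undefined AUC and is
    reported as ``None``. Cases whose score for a class is NaN (no reference
    sample of that class existed in their fold) are excluded for that class.
    """
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true, dtype=int)
    if scores.ndim != 2 or scores.shape[0] != true.shape[0]:
        raise ValueError("scores must be (n_cases, n_classes) aligned with true")
    out: list[Optional[float]] = []
    for m in range(scores.shape[1]):
        col = scores[:, m]
        ok = np.isfinite(col)
        y = (true[ok] == m).astype(int)
        if y.sum() == 0 or y.sum() == y.size or y.size == 0:
            out.append(None)
            continue
        out.append(float(roc_auc_score(y, col[ok])))
    return out


@dataclass(frozen=True)
class FoldRecord:
    """Outcome of a single leave-one-case-out fold."""

    held_out_case_id: str
    true_mrs: int
    predicted_mrs: int
    class_scores: tuple  # per-class max similarity; NaN when class absent
    tie: bool

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoldRecord):
            return NotImplemented
        return (
            self.held_out_case_id == other.held_out_case_id
            and self.true_mrs == other.true_mrs
            and self.predicted_mrs == other.predicted_mrs
            and self.tie == other.tie
            and np.allclose(self.class_scores, other.class_scores, equal_nan=True, rtol=0, atol=0)
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Full metric suite of one leave-one-case-out evaluation."""

    confusion: ConfusionMatrix
    per_class_precision: tuple
    per_class_recall: tuple
    per_class_accuracy: tuple  # == per-class recall, exposed under both names
    per_class_auc: tuple  # entries may be None (undefined)
    p_macro: float
    r_macro: float
    f1_macro: float
    mae_macro: float
    mcc: float
    folds: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        m = self.confusion.n_classes
        for name in ("per_class_precision", "per_class_recall", "per_class_accuracy", "per_class_auc"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} must have one entry per class ({m})")
        if not np.allclose(self.per_class_accuracy, self.per_class_recall):
            raise ValueError("per-class accuracy must equal per-class recall")
        expect = 0.0 if self.p_macro + self.r_macro == 0 else 2 * self.p_macro * self.r_macro / (self.p_macro + self.r_macro)
        if abs(self.f1_macro - expect) > 1e-9:
            raise ValueError("f1_macro inconsistent with macro precision/recall")

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.table.tolist(),
            "per_class_precision": list(self.per_class_precision),
            "per_class_recall": list(self.per_class_recall),
            "per_class_accuracy": list(self.per_class_accuracy),
            "per_class_auc": list(self.per_class_auc),
            "p_macro": self.p_macro,
            "r_macro": self.r_macro,
            "f1_macro": self.f1_macro,
            "mae_macro": self.mae_macro,
            "mcc": self.mcc,
            "folds": [
                {
                    "held_out_case_id": f.held_out_case_id,
                    "true_mrs": f.true_mrs,
                    "predicted_mrs": f.predicted_mrs,
                    "class_scores": [None if not np.isfinite(s) else float(s) for s in f.class_scores],
                    "tie": f.tie,
                }
                for f in self.folds
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        folds = tuple(
            FoldRecord(
                held_out_case_id=f["held_out_case_id"],
                true_mrs=int(f["true_mrs"]),
                predicted_mrs=int(f["predicted_mrs"]),
                class_scores=tuple(np.nan if s is None else float(s) for s in f["class_scores"]),
                tie=bool(f["tie"]),
            )
            for f in d.get("folds", [])
        )
        return cls(
            confusion=ConfusionMatrix(np.asarray(d["confusion"], dtype=int)),
            per_class_precision=tuple(d["per_class_precision"]),
            per_class_recall=tuple(d["per_class_recall"]),
            per_class_accuracy=tuple(d["per_class_accuracy"]),
            per_class_auc=tuple(d["per_class_auc"]),
            p_macro=float(d["p_macro"]),
            r_macro=float(d["r_macro"]),
            f1_macro=float(d["f1_macro"]),
            mae_macro=float(d["mae_macro"]),
            mcc=float(d["mcc"]),
            folds=folds,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvaluationReport):
            return NotImplemented
        mine, theirs = dataclasses.asdict(self), dataclasses.asdict(other)
        scalar_keys = [k for k in mine if k not in ("confusion", "folds")]
        return (
            self.confusion == other.confusion
            and all(
                np.array_equal(np.asarray(mine[k], dtype=object), np.asarray(theirs[k], dtype=object))
                for k in scalar_keys
            )
            and self.folds == other.folds
        )


def build_report(folds: Sequence[FoldRecord], n_classes: int) -> EvaluationReport:
    """Aggregate leave-one-out fold outcomes into the full metric suite."""
    if not folds:
        raise ValueError("no folds to aggregate")
    true = [f.true_mrs for f in folds]
    pred = [f.predicted_mrs for f in folds]
    cm = confusion_from_labels(true, pred, n_classes)
    precision, recall = per_class_pr(cm)
    p, r, f1 = macro_prf(precision, recall)
    scores = np.asarray([f.class_scores for f in folds], dtype=float)
    auc = per_class_auc(scores, true)
    return EvaluationReport(
        confusion=cm,
        per_class_precision=tuple(precision.tolist()),
        per_class_recall=tuple(recall.tolist()),
        per_class_accuracy=tuple(recall.tolist()),
        per_class_auc=tuple(auc),
        p_macro=p,
        r_macro=r,
        f1_macro=f1,
        mae_macro=macro_mae(true, pred, n_classes),
        mcc=mcc_multiclass(cm),
        folds=tuple(folds),
    )
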