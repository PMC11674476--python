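"""Evaluation metrics: accuracy, macro precision/recall, F1, MCC.

All five scores are derived from a single confusion matrix (rows = true
class, columns = predicted class).  Multiclass precision and recall are
macro-averaged one-vs-rest values; F1 is the harmonic mean of the *macro*
precision and recall aggregates.  The Matthews correlation coefficient is
reported, by default, as the macro average of the per-class one-vs-rest
binary MCC; the multiclass matrix-correlation generalization is available
via ``multiclass="matrix"``.  Any zero denominator contributes 0, never
NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_matrix",
    "accuracy",
    "precision_recall_f1",
    "mcc",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class count tallies; rows = truth, columns = prediction."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (m < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    # one-vs-rest reductions, one value per class
    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fn - self.fp


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict())

    def csv_row(self, ndigits: int = 6) -> str:
        return ",".join(f"{v:.{ndigits}f}" for v in (self.accuracy, self.precision, self.recall, self.f1, self.mcc))

    CSV_HEADER = "accuracy,precision,recall,f1,mcc"


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return ConfusionCounts(m)


def accuracy(cc: ConfusionCounts) -> float:
    """Proportion of correctly predicted samples (trace / total)."""
    if cc.total == 0:
        raise ValueError("empty confusion matrix")
    return float(cc.tp.sum() / cc.total)


def precision_recall_f1(cc: ConfusionCounts):
    """Macro precision and recall; F1 = harmonic mean of the two macros."""
    if cc.total == 0:
        raise ValueError("empty confusion matrix")
    prec = _safe_div(cc.tp, cc.tp + cc.fp).mean()
    rec = _safe_div(cc.tp, cc.tp + cc.fn).mean()
    f1 = 2.0 / (1.0 / prec + 1.0 / rec) if prec > 0 and rec > 0 else 0.0
    return float(prec), float(rec), float(f1)


def mcc(cc: ConfusionCounts, multiclass: str = "macro_ovr") -> float:
    """Matthews correlation coefficient in [-1, 1].

    Binary tables use the textbook formula exactly.  For more classes,
    ``macro_ovr`` (default) averages per-class one-vs-rest binary MCCs;
    ``matrix`` computes the R_k matrix-correlation generalization.
    """
    if cc.total == 0:
        raise ValueError("empty confusion matrix")
    if cc.n_classes == 2 or multiclass == "macro_ovr":
        vals = [
            _binary_mcc(tp, tn, fp, fn)
            for tp, tn, fp, fn in zip(cc.tp, cc.tn, cc.fp, cc.fn)
        ]
        if cc.n_classes == 2:
            # both one-vs-rest reductions of a 2x2 table are identical
            return float(vals[0])
        return float(np.mean(vals))
    if multiclass == "matrix":
        m = cc.matrix.astype(float)
        t = m.sum(axis=1)  # true occurrences
        p = m.sum(axis=0)  # predicted occurrences
        n = m.sum()
        num = np.trace(m) * n - t @ p
        den = np.sqrt(n**2 - p @ p) * np.sqrt(n**2 - t @ t)
        return float(num / den) if den > 0 else 0.0
    raise ValueError(f"unknown multiclass mode {multiclass!r}")


def _binary_mcc(tp, tn, fp, fn) -> float:
    tp, tn, fp, fn = (float(v) for v in (tp, tn, fp, fn))
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(den)


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def evaluate_predictions(y_true, y_pred, n_classes: int, multiclass_mcc: str = "macro_ovr") -> MetricReport:
    """All five metrics from raw label vectors."""
    cc = confusion_matrix(y_true, y_pred, n_classes)
    prec, rec, f1 = precision_recall_f1(cc)
    return MetricReport(
        accuracy=accuracy(cc),
        precision=prec,
        recall=rec,
        f1=f1,
        mcc=mcc(cc, multiclass=multiclass_mcc),
    )
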