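"""Confusion-matrix metrics, k-fold cross-validation, ROC and sweeps.

Metric definitions (TP/FN/TN/FP are true/false positive/negative counts):

    Sn  = TP / (TP + FN)                    sensitivity (recall)
    Sp  = TN / (TN + FP)                    specificity
    Acc = (TP + TN) / (TP + FN + TN + FP)   accuracy
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

Cross-validation predictions are *pooled*: the per-fold predictions are
combined into one confusion matrix before metrics are computed, so each
window contributes exactly once. Report formatting follows the usual
convention of percentages to one decimal and MCC to two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .seqio import Fragment

Trainer = Callable[[Sequence[Fragment], Sequence[Fragment], int],
                   Callable[[Sequence[Fragment]], np.ndarray]]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int((y_true & y_pred).sum()),
            fn=int((y_true & ~y_pred).sum()),
            tn=int((~y_true & ~y_pred).sum()),
            fp=int((~y_true & y_pred).sum()),
        )

    @classmethod
    def from_scores(
        cls, y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
    ) -> "ConfusionMatrix":
        return cls.from_labels(y_true, np.asarray(scores) >= threshold)


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: Optional[float] = None
    mcc_defined: bool = True

    def formatted(self) -> str:
        """Report row: percentages to 1 decimal, MCC to 2 decimals."""
        parts = [
            f"Sn={self.sn * 100:.1f}%",
            f"Sp={self.sp * 100:.1f}%",
            f"Acc={self.acc * 100:.1f}%",
            f"MCC={self.mcc:.2f}",
        ]
        if self.auc is not None:
            parts.append(f"AUC={self.auc:.3f}")
        return " ".join(parts)


def metrics(cm: ConfusionMatrix, auc: Optional[float] = None) -> Metrics:
    """Sn/Sp/Acc/MCC from a confusion matrix.

    An empty actual class is an error (Sn or Sp undefined). A zero MCC
    marginal (no predicted positives or no predicted negatives) yields
    MCC = 0 with ``mcc_defined=False``.
    """
    if cm.tp + cm.fn == 0:
        raise ValueError("no actual positives: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ValueError("no actual negatives: specificity undefined")
    sn = cm.tp / (cm.tp + cm.fn)
    sp = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    denom = (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tp + cm.fp) * (cm.tn + cm.fn)
    if denom == 0:
        return Metrics(sn=sn, sp=sp, acc=acc, mcc=0.0, auc=auc, mcc_defined=False)
    mcc = (cm.tp * cm.tn - cm.fn * cm.fp) / math.sqrt(denom)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """(FPR, TPR, AUC) swept over score thresholds; equal scores grouped;
    AUC by the trapezoid rule."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(labels, scores)
    return fpr, tpr, float(skmetrics.auc(fpr, tpr))


@dataclass
class CvResult:
    """Pooled cross-validation outcome."""

    pooled: ConfusionMatrix
    metrics: Metrics
    fold_matrices: list[ConfusionMatrix]
    scores: np.ndarray
    labels: np.ndarray
    fold_assignment: np.ndarray


def _fold_indices(
    n_pos: int, n_neg: int, k: int, seed: int, stratified: bool
) -> np.ndarray:
    """Fold id per fragment (positives first, then negatives)."""
    rng = np.random.default_rng(seed)
    if stratified:
        fold = np.empty(n_pos + n_neg, dtype=int)
        for offset, size in ((0, n_pos), (n_pos, n_neg)):
            ids = np.arange(size) % k
            rng.shuffle(ids)
            fold[offset : offset + size] = ids
    else:
        fold = np.arange(n_pos + n_neg) % k
        rng.shuffle(fold)
    return fold


def kfold_cv(
    trainer: Trainer,
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
    threshold: float = 0.5,
) -> CvResult:
    """k-fold cross-validation with pooled metrics.

    *trainer(pos, neg, seed)* must return a scorer mapping fragments to
    positive-class probabilities. Folds are stratified by class by default;
    the per-fold predictions are pooled into a single confusion matrix.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(positives) < k or len(negatives) < k:
        raise ValueError(
            f"each class must have at least k={k} members "
            f"(got {len(positives)} positives, {len(negatives)} negatives)"
        )
    frags = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    fold = _fold_indices(len(positives), len(negatives), k, seed, stratified)

    scores = np.empty(len(frags))
    fold_matrices: list[ConfusionMatrix] = []
    for f in range(k):
        test_mask = fold == f
        train_pos = [fr for fr, m, yy in zip(frags, test_mask, y) if not m and yy == 1]
        train_neg = [fr for fr, m, yy in zip(frags, test_mask, y) if not m and yy == 0]
        scorer = trainer(train_pos, train_neg, seed + f)
        test_frags = [fr for fr, m in zip(frags, test_mask) if m]
        s = np.asarray(scorer(test_frags))
        scores[test_mask] = s
        fold_matrices.append(ConfusionMatrix.from_scores(y[test_mask], s, threshold))

    pooled = ConfusionMatrix.from_scores(y, scores, threshold)
    _, _, auc = roc_points(scores, y)
    return CvResult(
        pooled=pooled, metrics=metrics(pooled, auc=auc), fold_matrices=fold_matrices,
        scores=scores, labels=y, fold_assignment=fold,
    )


def sweep_windows(
    trainer: Trainer,
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    windows: Sequence[int] = (11, 13, 15, 17, 19, 21, 23, 25),
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate at several window lengths by trimming the fragments.

    Requires fragments at least as wide as the largest requested window.
    """
    rows = []
    for w in windows:
        if w % 2 != 1:
            raise ValueError(f"window length must be odd, got {w}")
        n = w // 2
        res = kfold_cv(
            trainer, [f.trimmed(n) for f in positives], [f.trimmed(n) for f in negatives],
            k=k, seed=seed,
        )
        rows.append(_metrics_row({"window": w}, res.metrics))
    return pd.DataFrame(rows)


def sweep_k(
    trainer: Trainer,
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    ks: Sequence[int] = (5, 6, 7, 8, 9, 10),
    seed: int = 0,
) -> pd.DataFrame:
    """Stability of pooled CV metrics across fold counts."""
    rows = []
    for k in ks:
        res = kfold_cv(trainer, positives, negatives, k=k, seed=seed)
        rows.append(_metrics_row({"k": k}, res.metrics))
    return pd.DataFrame(rows)


def sweep_schemes(
    trainer_factory: Callable[[str, Optional[int]], Trainer],
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    schemes: Sequence[tuple[str, Optional[int]]] = (
        ("aac", None), ("aapc", None), ("cksaap", 1), ("cksaap", 2), ("cksaap", 3),
    ),
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare feature encodings under identical CV conditions."""
    rows = []
    for scheme, spacing in schemes:
        res = kfold_cv(trainer_factory(scheme, spacing), positives, negatives, k=k, seed=seed)
        name = scheme if spacing is None else f"{scheme}-k{spacing}"
        rows.append(_metrics_row({"scheme": name}, res.metrics))
    return pd.DataFrame(rows)


def _metrics_row(head: dict, m: Metrics) -> dict:
    return {
        **head, "sn": m.sn, "sp": m.sp, "acc": m.acc, "mcc": m.mcc,
        **({"auc": m.auc} if m.auc is not None else {}),
    }
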