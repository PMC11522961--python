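"""Screening metrics and vote-sum threshold analysis.

The ensemble exposes only an integer score — the number of trees voting
MCI — so every candidate threshold ``th`` in ``0..n_trees`` defines one
operating point: classify MCI when the sum reaches ``th``.  The threshold
is chosen from the F-beta curve; for screening, beta = 2 weights recall
four times precision, because a missed MCI case (a false negative) costs
far more than a reviewable false positive, while still penalising the
trivial everyone-is-MCI classifier at ``th = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .engine import DiagnosisResult

__all__ = [
    "MetricsReport",
    "ThresholdCurves",
    "confusion_counts",
    "f_beta",
    "threshold_curves",
    "select_threshold",
    "roc_auc",
    "compute_report",
]


def f_beta(precision: float, recall: float, beta: float) -> float:
    """F-beta score; beta > 1 favours recall, beta < 1 favours precision.

    Defined as 0 when both precision and recall are 0.
    """
    if not 0.0 <= precision <= 1.0 or not 0.0 <= recall <= 1.0:
        raise ValueError("precision and recall must lie in [0, 1]")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    b2 = beta * beta
    denom = b2 * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + b2) * precision * recall / denom


def confusion_counts(
    results: Sequence[DiagnosisResult],
    gold: Sequence[int],
    include: str = "automatic_only",
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) over the included cases.

    ``include`` is ``automatic_only`` (complete-data diagnoses) or
    ``all_conclusive`` (adds conclusive partial MCI cases).  Undetermined
    cases are always excluded.
    """
    if include not in ("automatic_only", "all_conclusive"):
        raise ValueError(f"unknown include policy {include!r}")
    if len(results) != len(gold):
        raise ValueError(
            f"results ({len(results)}) and gold ({len(gold)}) lengths differ"
        )
    tp = fp = tn = fn = 0
    for r, g in zip(results, gold):
        if g not in (0, 1):
            raise ValueError(f"gold labels must be 0 or 1, got {g!r}")
        if r.label == "Undetermined":
            continue
        if include == "automatic_only" and r.status != "automatic":
            continue
        if include == "all_conclusive" and not r.conclusive:
            continue
        pred = 1 if r.label == "MCI" else 0
        if pred == 1 and g == 1:
            tp += 1
        elif pred == 1 and g == 0:
            fp += 1
        elif pred == 0 and g == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


@dataclass
class ThresholdCurves:
    """Per-threshold operating points of the vote-sum classifier.

    ``precision`` is NaN at thresholds with no predicted positives and
    ``recall`` is NaN if the gold labels contain no positive cases; such
    undefined points are listed in ``undefined_thresholds``.
    """

    n_trees: int
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    betas: tuple[float, ...]
    f_scores: dict[float, np.ndarray]
    undefined_thresholds: list[int] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "threshold": self.thresholds,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "fpr": self.fpr,
        }
        for b in self.betas:
            data[f"f{b:g}"] = self.f_scores[b]
        return pd.DataFrame(data)


def threshold_curves(
    vote_sums: Sequence[int],
    gold: Sequence[int],
    n_trees: int,
    betas: Sequence[float] = (0.5, 1.0, 2.0, 3.0),
) -> ThresholdCurves:
    """Confusion-derived curves for every threshold 0..n_trees.

    ``th = 0`` is the trivial all-MCI classifier (recall exactly 1) and is
    kept for curve completeness but never selectable.
    """
    sums = np.asarray(vote_sums, dtype=float)
    y = np.asarray(gold, dtype=int)
    if len(sums) != len(y):
        raise ValueError("vote_sums and gold must have equal length")
    if len(sums) == 0:
        raise ValueError("no cases to evaluate")
    if sums.min() < 0 or sums.max() > n_trees:
        raise ValueError(f"vote sums must lie in [0, {n_trees}]")
    betas = tuple(float(b) for b in betas)
    ths = np.arange(n_trees + 1)
    tp = np.empty(len(ths), dtype=int)
    fp = np.empty_like(tp)
    tn = np.empty_like(tp)
    fn = np.empty_like(tp)
    for i, th in enumerate(ths):
        pred = sums >= th
        tp[i] = int(np.sum(pred & (y == 1)))
        fp[i] = int(np.sum(pred & (y == 0)))
        tn[i] = int(np.sum(~pred & (y == 0)))
        fn[i] = int(np.sum(~pred & (y == 1)))
    n_pos = tp + fn
    n_neg = fp + tn
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        recall = np.where(n_pos > 0, tp / np.maximum(n_pos, 1), np.nan)
        fpr = np.where(n_neg > 0, fp / np.maximum(n_neg, 1), np.nan)
    f_scores: dict[float, np.ndarray] = {}
    for b in betas:
        vals = np.empty(len(ths))
        for i in range(len(ths)):
            if tp[i] == 0:
                vals[i] = 0.0
            else:  # tp > 0 implies precision and recall both defined and > 0
                vals[i] = f_beta(float(precision[i]), float(recall[i]), b)
        f_scores[b] = vals
    undefined = [
        int(th)
        for i, th in enumerate(ths)
        if np.isnan(precision[i]) or np.isnan(recall[i])
    ]
    return ThresholdCurves(
        n_trees=n_trees,
        thresholds=ths,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        precision=precision,
        recall=recall,
        fpr=fpr,
        betas=betas,
        f_scores=f_scores,
        undefined_thresholds=undefined,
    )


def select_threshold(
    curves: ThresholdCurves,
    criterion: str = "max_f_beta",
    beta: float = 2.0,
) -> int:
    """Pick the operating threshold from the curves.

    ``max_f_beta``: argmax of the F-beta curve over th >= 1 (th = 0 is the
    trivial classifier and is excluded); ``max_recall_nontrivial``: the
    minimum th >= 1 maximising recall.  Ties always resolve to the lowest
    threshold.
    """
    if criterion == "max_f_beta":
        values = curves.f_scores.get(float(beta))
        if values is None:
            raise ValueError(f"beta {beta} not present in curves (betas={curves.betas})")
    elif criterion == "max_recall_nontrivial":
        values = curves.recall
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    candidate = np.array(values[1:], dtype=float)
    candidate[np.isnan(candidate)] = -np.inf
    return int(np.argmax(candidate)) + 1  # argmax returns the first (lowest) tie


def roc_auc(vote_sums: Sequence[int], gold: Sequence[int]) -> float:
    """Rank-based ROC-AUC using the integer vote sum as the score."""
    y = np.asarray(gold, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC-AUC needs both classes present in gold")
    return float(roc_auc_score(y, np.asarray(vote_sums, dtype=float)))


@dataclass
class MetricsReport:
    """Confusion-derived summary at one operating threshold."""

    threshold: int
    beta: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    f_beta: float
    roc_auc: float | None
    n_evaluated: int
    include: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_text(self) -> str:
        lines = [
            f"cases evaluated : {self.n_evaluated} ({self.include})",
            f"threshold (th)  : {self.threshold}",
            f"TP/FP/TN/FN     : {self.tp}/{self.fp}/{self.tn}/{self.fn}",
            f"accuracy        : {self.accuracy:.3f}",
            f"precision       : {self.precision:.3f}",
            f"recall          : {self.recall:.3f}",
            f"F1              : {self.f1:.3f}",
            f"F{self.beta:g}              : {self.f_beta:.3f}",
        ]
        if self.roc_auc is not None:
            lines.append(f"ROC-AUC         : {self.roc_auc:.3f}")
        return "\n".join(lines)


def compute_report(
    results: Sequence[DiagnosisResult],
    gold: Sequence[int],
    threshold: int,
    beta: float = 2.0,
    include: str = "automatic_only",
) -> MetricsReport:
    """Metrics over a classified batch at its operating threshold.

    ROC-AUC is computed over the automatic cases only (partial sums are not
    comparable across differing numbers of active trees) and is ``None``
    when those cases are single-class.
    """
    tp, fp, tn, fn = confusion_counts(results, gold, include=include)
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    auto = [
        (r.vote_sum, g)
        for r, g in zip(results, gold)
        if r.status == "automatic" and g in (0, 1)
    ]
    auc: float | None = None
    if auto:
        sums, ys = zip(*auto)
        if len(set(ys)) == 2:
            auc = roc_auc(sums, ys)
    return MetricsReport(
        threshold=threshold,
        beta=float(beta),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f_beta(precision, recall, 1.0),
        f_beta=f_beta(precision, recall, beta),
        roc_auc=auc,
        n_evaluated=n,
        include=include,
    )
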