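"""Confusion-matrix metric suite, ROC/AUROC with bootstrap CI, and the
PPV/NPV-by-threshold table.

Rates (sensitivity, specificity, accuracy, PPV, NPV) are reported in
percent; precision, MCC, F1 and AUROC as fractions.  MCC uses the standard
four-factor denominator, with the convention MCC = 0 when any marginal is
zero (constant predictions or constant labels).  AUROC is computed both as
the trapezoidal area over all score thresholds and as the normalized
Mann-Whitney statistic with ties counted 1/2 — the two are asserted equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "compute_metrics",
    "f1_aggregate",
    "roc_auroc",
    "bootstrap_auroc_ci",
    "ppv_npv_table",
]


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    """A 2x2 tally: true/false positives and negatives."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise EvaluationError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class MetricReport:
    """The full metric suite for one confusion matrix.

    ``None`` fields are undefined ratios (zero denominator); the reason is
    recorded in ``notes`` rather than propagating NaN.
    """

    sensitivity: float | None  # percent; == recall * 100
    specificity: float | None  # percent
    accuracy: float | None  # percent
    precision: float | None  # fraction
    recall: float | None  # fraction
    mcc: float
    f1: dict = field(default_factory=dict)  # per_class / macro / weighted / micro
    auroc: float | None = None
    auroc_ci: tuple[float, float] | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "mcc": self.mcc,
            "f1": self.f1,
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci) if self.auroc_ci else None,
            "notes": self.notes,
        }


def confusion_counts(labels, predictions, positive=True) -> ConfusionCounts:
    """Tally a 2x2 confusion matrix; ``positive`` designates the positive label."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise EvaluationError(
            f"labels and predictions differ in length: {labels.shape} vs {predictions.shape}"
        )
    actual_pos = labels == positive
    pred_pos = predictions == positive
    return ConfusionCounts(
        tp=int(np.sum(actual_pos & pred_pos)),
        fp=int(np.sum(~actual_pos & pred_pos)),
        tn=int(np.sum(~actual_pos & ~pred_pos)),
        fn=int(np.sum(actual_pos & ~pred_pos)),
    )


def _ratio(num: int, den: int, notes: list[str], what: str) -> float | None:
    if den == 0:
        notes.append(f"{what} undefined: zero denominator")
        return None
    return num / den


def matthews_corrcoef(c: ConfusionCounts) -> float:
    """Standard four-factor MCC; 0 by convention when any marginal is zero."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in denom_factors):
        return 0.0
    num = tp * tn - fp * fn
    return num / math.sqrt(math.prod(denom_factors))


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Sensitivity/specificity/accuracy (percent), precision/recall, MCC, F1."""
    if c.total == 0:
        raise EvaluationError("empty confusion matrix")
    notes: list[str] = []
    sens = _ratio(c.tp, c.tp + c.fn, notes, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, notes, "specificity")
    acc = (c.tp + c.tn) / c.total
    prec = _ratio(c.tp, c.tp + c.fp, notes, "precision")
    rec = sens
    f1 = f1_aggregate({"positive": c, "negative": _swap(c)})
    return MetricReport(
        sensitivity=None if sens is None else sens * 100,
        specificity=None if spec is None else spec * 100,
        accuracy=acc * 100,
        precision=prec,
        recall=rec,
        mcc=matthews_corrcoef(c),
        f1=f1,
        notes=notes,
    )


def _swap(c: ConfusionCounts) -> ConfusionCounts:
    """The same 2x2 table seen from the other class."""
    return ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)


def _f1_of(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 0.0
    return 2 * c.tp / denom


def f1_aggregate(per_class: dict[str, ConfusionCounts]) -> dict:
    """Per-class, macro, support-weighted and micro F1.

    Micro-F1 pools counts before computing F1; for a complete binary
    confusion it equals accuracy, which is how the study's printed binary
    "F1 Score" column behaves.
    """
    if not per_class:
        raise EvaluationError("f1_aggregate: empty class set")
    scores = {k: _f1_of(c) for k, c in per_class.items()}
    supports = {k: c.tp + c.fn for k, c in per_class.items()}
    total_support = sum(supports.values())
    macro = float(np.mean(list(scores.values())))
    if total_support == 0:
        weighted = 0.0
    else:
        weighted = sum(scores[k] * supports[k] for k in scores) / total_support
    pooled = ConfusionCounts(
        tp=sum(c.tp for c in per_class.values()),
        fp=sum(c.fp for c in per_class.values()),
        tn=sum(c.tn for c in per_class.values()),
        fn=sum(c.fn for c in per_class.values()),
    )
    return {"per_class": scores, "macro": macro, "weighted": weighted, "micro": _f1_of(pooled)}


def _auroc_trapezoid(scores: np.ndarray, y: np.ndarray) -> float:
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # collapse tied scores to a single ROC vertex
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(np.trapezoid(tpr, fpr))


def _auroc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = sps.rankdata(scores)  # average ranks count ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_auroc(scores, labels) -> float:
    """Full-curve AUROC; trapezoid and Mann-Whitney forms computed and checked."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise EvaluationError("roc_auroc: both classes must be present")
    a_trap = _auroc_trapezoid(scores, y)
    a_rank = _auroc_rank(scores, y)
    if abs(a_trap - a_rank) > 1e-12:
        raise EvaluationError(
            f"AUROC formulations disagree: trapezoid {a_trap!r} vs rank {a_rank!r}"
        )
    return a_rank


def bootstrap_auroc_ci(
    scores, labels, reps: int = 2000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUROC."""
    if reps < 100:
        raise EvaluationError("bootstrap_auroc_ci: reps must be >= 100")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("bootstrap_auroc_ci: both classes must be present")
    rng = np.random.default_rng(seed)
    stat = np.empty(reps)
    for i in range(reps):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([bp, bn])
        yy = np.r_[np.ones(len(bp), dtype=int), np.zeros(len(bn), dtype=int)]
        stat[i] = _auroc_rank(s, yy)
    lo, hi = np.quantile(stat, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def ppv_npv_table(scores, labels, thresholds) -> pd.DataFrame:
    """PPV/NPV at symmetric score cut-offs.

    At cut-off t a sample is called positive (early) when its score >= t
    and negative (late) when its score <= 1 - t; samples in between
    abstain, so positive and negative calls need not partition the set.
    Empty call sets report 0.00 with a flag.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    rows = []
    for t in thresholds:
        if not (0.0 <= t <= 1.0):
            raise EvaluationError(f"threshold outside [0,1]: {t}")
        pos_call = scores >= t
        # round the complementary cut so 1-0.9 is 0.1 exactly, not 0.0999...
        neg_call = scores <= round(1.0 - t, 12)
        n_pos = int(pos_call.sum())
        n_pos_ok = int((pos_call & (y == 1)).sum())
        n_neg = int(neg_call.sum())
        n_neg_ok = int((neg_call & (y == 0)).sum())
        ppv = 100.0 * n_pos_ok / n_pos if n_pos else 0.0
        npv = 100.0 * n_neg_ok / n_neg if n_neg else 0.0
        rows.append(
            {
                "threshold": t,
                "n_pred_pos": n_pos,
                "n_correct_pos": n_pos_ok,
                "ppv": ppv,
                "n_pred_neg": n_neg,
                "n_correct_neg": n_neg_ok,
                "npv": npv,
                "empty_calls": n_pos == 0 or n_neg == 0,
            }
        )
    return pd.DataFrame(rows)
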