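"""Directional single-transcript threshold classifiers ranked by point AUROC.

Each transcript gets a one-dimensional classifier: pick the direction from
the class means (the class with the greater mean is called when expression
is high), then sweep every observed expression value as a candidate
cut-point and keep the one maximizing the point AUROC, defined as
(sensitivity + specificity) / 2 — the trapezoidal area of the three-point
ROC {(0,0), (FPR,TPR), (1,1)} of a single hard threshold.  Transcripts are
then ranked by this score; panels are the transcripts above an AUROC
cutoff (0.60 for the stage task, 0.85 for cancer-vs-normal).

The prediction rule is inclusive: a sample is assigned to the higher-mean
class iff its value >= threshold.  On ties the smallest maximizing
threshold is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .evaluate import ConfusionCounts
from .expression_io import DataError, ExpressionMatrix, SampleLabels

__all__ = [
    "ThresholdModel",
    "fit_threshold_model",
    "rank_features",
    "select_by_auroc",
    "wilcoxon_rank_test",
    "RANKED_TABLE_COLUMNS",
]

RANKED_TABLE_COLUMNS = [
    "transcript_id", "direction", "threshold", "point_auroc",
    "mean_pos", "mean_neg", "p_value", "adjusted_p",
]


@dataclass
class ThresholdModel:
    """One transcript's directional cut-point classifier.

    ``direction`` is ``positive_high`` when the positive class (early, or
    cancer — the caller's convention) has the greater mean.  ``degenerate``
    marks transcripts with no separation (constant values or equal means).
    """

    transcript_id: str
    direction: str
    threshold: float
    point_auroc: float
    confusion_at_threshold: ConfusionCounts
    mean_pos: float
    mean_neg: float
    degenerate: bool = False

    def predict(self, values: np.ndarray) -> np.ndarray:
        """True = positive-class call, per the inclusive >= rule."""
        values = np.asarray(values, dtype=float)
        high = values >= self.threshold
        return high if self.direction == "positive_high" else ~high


def _best_cut(values_pos: np.ndarray, values_neg: np.ndarray, direction: str):
    """Scan the sorted unique observed values; return (threshold, auroc, sens, spec).

    For ``positive_high`` a positive call is value >= t; for ``negative_high``
    the >= t side is the negative call.  Vectorized via searchsorted.
    """
    n_pos, n_neg = len(values_pos), len(values_neg)
    candidates = np.unique(np.concatenate([values_pos, values_neg]))
    sp = np.sort(values_pos)
    sn = np.sort(values_neg)
    # count of values >= t for each candidate t
    pos_ge = n_pos - np.searchsorted(sp, candidates, side="left")
    neg_ge = n_neg - np.searchsorted(sn, candidates, side="left")
    if direction == "positive_high":
        sens = pos_ge / n_pos
        spec = 1.0 - neg_ge / n_neg
    else:
        sens = 1.0 - pos_ge / n_pos
        spec = neg_ge / n_neg
    auroc = (sens + spec) / 2.0
    best = int(np.argmax(auroc))  # argmax takes the first (smallest) maximizer
    return float(candidates[best]), float(auroc[best]), float(sens[best]), float(spec[best])


def fit_threshold_model(
    values_pos, values_neg, transcript_id: str = ""
) -> ThresholdModel:
    """Fit the directional threshold classifier for one transcript.

    Direction is set by comparing class means; candidate thresholds are the
    sorted unique observed values; the returned threshold maximizes
    (sens+spec)/2, smallest first on ties.  Constant input yields a
    degenerate model with point AUROC 0.5.
    """
    vp = np.asarray(values_pos, dtype=float)
    vn = np.asarray(values_neg, dtype=float)
    if vp.size == 0 or vn.size == 0:
        raise DataError("fit_threshold_model: both classes must be non-empty")
    if not (np.isfinite(vp).all() and np.isfinite(vn).all()):
        raise DataError("fit_threshold_model: non-finite expression value")
    mean_pos, mean_neg = float(vp.mean()), float(vn.mean())
    # equal means default to positive_high with the degenerate flag raised
    direction = "positive_high" if mean_pos >= mean_neg else "negative_high"
    threshold, auroc, sens, spec = _best_cut(vp, vn, direction)
    degenerate = mean_pos == mean_neg or auroc <= 0.5
    tp = int(round(sens * vp.size))
    fn = vp.size - tp
    tn = int(round(spec * vn.size))
    fp = vn.size - tn
    return ThresholdModel(
        transcript_id=transcript_id,
        direction=direction,
        threshold=threshold,
        point_auroc=auroc,
        confusion_at_threshold=ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn),
        mean_pos=mean_pos,
        mean_neg=mean_neg,
        degenerate=degenerate,
    )


def wilcoxon_rank_test(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    positive_class: str = "early",
    negative_class: str = "late",
) -> pd.DataFrame:
    """Two-sided rank-sum test per transcript, BH-adjusted across transcripts.

    Exact null distribution when the pooled n is <= 25 with no ties; normal
    approximation with tie correction otherwise.
    """
    cls = labels.class_array(matrix.sample_ids)
    pos_mask = cls == positive_class
    neg_mask = cls == negative_class
    if pos_mask.sum() < 2 or neg_mask.sum() < 2:
        raise DataError("wilcoxon_rank_test needs >= 2 samples in each class")
    X = matrix.data.to_numpy(dtype=float)
    xp, xn = X[:, pos_mask], X[:, neg_mask]
    n = xp.shape[1] + xn.shape[1]
    pvals = np.empty(X.shape[0])
    constant = np.array([np.all(row == row[0]) for row in X])
    pvals[constant] = 1.0
    rest = np.flatnonzero(~constant)
    if n <= 25:
        for i in rest:
            pooled = np.concatenate([xp[i], xn[i]])
            has_ties = len(np.unique(pooled)) < n
            method = "exact" if not has_ties else "asymptotic"
            pvals[i] = sps.mannwhitneyu(
                xp[i], xn[i], alternative="two-sided", method=method
            ).pvalue
    elif rest.size:
        # large-sample: one vectorized normal-approximation call (tie-corrected)
        res = sps.mannwhitneyu(
            xp[rest], xn[rest], alternative="two-sided", method="asymptotic", axis=1
        )
        pvals[rest] = res.pvalue
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"p_value": pvals, "adjusted_p": adjusted}, index=matrix.transcript_ids
    ).rename_axis("transcript_id")


def rank_features(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    positive_class: str = "early",
    negative_class: str = "late",
    with_pvalues: bool = True,
) -> pd.DataFrame:
    """Fit a threshold model per transcript and rank by point AUROC.

    Returns the ranked feature table (columns :data:`RANKED_TABLE_COLUMNS`),
    sorted by point AUROC descending with ties broken by transcript ID.
    """
    cls = labels.class_array(matrix.sample_ids)
    pos_mask = cls == positive_class
    neg_mask = cls == negative_class
    if not pos_mask.any() or not neg_mask.any():
        raise DataError(
            f"rank_features: classes {positive_class!r}/{negative_class!r} not both present"
        )
    X = matrix.data.to_numpy(dtype=float)
    rows = []
    for i, tid in enumerate(matrix.transcript_ids):
        m = fit_threshold_model(X[i, pos_mask], X[i, neg_mask], transcript_id=tid)
        rows.append((tid, m.direction, m.threshold, m.point_auroc, m.mean_pos, m.mean_neg))
    table = pd.DataFrame(rows, columns=RANKED_TABLE_COLUMNS[:6])
    if with_pvalues:
        pv = wilcoxon_rank_test(matrix, labels, positive_class, negative_class)
        table = table.merge(pv, left_on="transcript_id", right_index=True)
    else:
        table["p_value"] = np.nan
        table["adjusted_p"] = np.nan
    table = table.sort_values(
        ["point_auroc", "transcript_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def select_by_auroc(table: pd.DataFrame, cutoff: float):
    """Panel of transcripts with point AUROC >= cutoff (inclusive), rank order kept."""
    from .feature_select import FeaturePanel  # local import to avoid a cycle

    if not (0.0 <= cutoff <= 1.0):
        raise DataError(f"AUROC cutoff must be in [0,1], got {cutoff}")
    kept = table[table["point_auroc"] >= cutoff]
    return FeaturePanel(
        transcript_ids=kept["transcript_id"].tolist(),
        method="threshold_auroc",
        parameters={"cutoff": cutoff},
        scores=dict(zip(kept["transcript_id"], kept["point_auroc"])),
    )
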