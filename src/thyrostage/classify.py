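"""Train, tune and apply RBF margin classifiers over a feature panel.

A deployable :class:`TrainedStageModel` freezes the feature panel, the
training-set normalization statistics (the model applies its own
log2(FPKM+1) and Z-score chain at prediction time), the fitted kernel
parameters and a decision threshold.  Probability scores come from a
monotone sigmoid (Platt) calibration fitted on out-of-fold decision values
within the training set, so the archive is fully plain-text: the RBF
decision function is recomputed from the stored support vectors and dual
coefficients.

Hyperparameters are tuned by stratified k-fold grid search over
gamma in [1e-3, 10] and cost in [1, 10].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .evaluate import MetricReport, compute_metrics, confusion_counts
from .expression_io import DataError, ExpressionMatrix, SampleLabels
from .feature_select import FeaturePanel
from .preprocess import NormalizationStats, align_features, apply_zscore, fit_zscore, log2_transform

__all__ = [
    "GridSpec",
    "TrainedStageModel",
    "grid_search_cv",
    "train_binary",
    "train_multiclass_ovr",
    "predict_scores",
    "choose_decision_threshold",
    "cross_validate",
]

ARCHIVE_SCHEMA = 1

#: Default grid: log-spaced gamma spanning [1e-3, 10], integer costs in [1, 10].
DEFAULT_GAMMA = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
DEFAULT_COST = tuple(float(c) for c in range(1, 11))


@dataclass
class GridSpec:
    gamma_values: tuple = DEFAULT_GAMMA
    cost_values: tuple = DEFAULT_COST
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise DataError("GridSpec: folds must be >= 2")
        if not self.gamma_values or not self.cost_values:
            raise DataError("GridSpec: empty grid")


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid p = 1 / (1 + exp(a*d + b)) with smoothed targets.

    Fitted by minimizing the cross-entropy against targets
    (N+ + 1)/(N+ + 2) and 1/(N- + 2); constant decision values fall back
    to a flat sigmoid at the positive-class prevalence.
    """
    d = np.asarray(decision, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if d.max() == d.min():
        prev = (n_pos + 1) / (len(y) + 2)
        return 0.0, float(np.log((1 - prev) / prev))
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = np.clip(a * d + b, -500, 500)
        p = 1.0 / (1.0 + np.exp(z))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))

    b0 = float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    res = minimize(nll, x0=np.array([-1.0, b0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    a, b = res.x
    if a > 0:  # calibration must be monotone increasing in the decision value
        a = 0.0
        prev = (n_pos + 1) / (len(y) + 2)
        b = float(np.log((1 - prev) / prev))
    return float(a), float(b)


@dataclass
class RbfScorer:
    """A binary RBF decision function plus Platt calibration, in plain data.

    ``decision(X)`` reproduces the fitted SVC's decision_function from the
    stored support vectors; positive decisions favor the positive class.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    cost: float
    platt_a: float
    platt_b: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sq = (
            np.sum(self.support_vectors**2, axis=1)[None, :]
            + np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def probability(self, X: np.ndarray) -> np.ndarray:
        z = np.clip(self.platt_a * self.decision(X) + self.platt_b, -500, 500)
        return 1.0 / (1.0 + np.exp(z))

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "cost": self.cost,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RbfScorer":
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            cost=float(d["cost"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
        )


def _fit_scorer(X: np.ndarray, y: np.ndarray, gamma: float, cost: float,
                seed: int, calib_folds: int = 5) -> RbfScorer:
    """Fit an SVC, extract its parameters, and calibrate on out-of-fold decisions."""
    clf = SVC(kernel="rbf", C=cost, gamma=gamma)
    clf.fit(X, y)
    folds = min(calib_folds, int(np.bincount(y).min()))
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        d_oof = cross_val_predict(
            SVC(kernel="rbf", C=cost, gamma=gamma), X, y,
            cv=cv, method="decision_function",
        )
    else:
        d_oof = clf.decision_function(X)
    a, b = _fit_platt(d_oof, y)
    return RbfScorer(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        gamma=float(gamma),
        cost=float(cost),
        platt_a=a,
        platt_b=b,
    )


@dataclass
class TrainedStageModel:
    """Frozen panel + normalization stats + fitted scorers + threshold."""

    kind: str  # "binary" or "multiclass"
    panel: FeaturePanel
    stats: NormalizationStats
    scorers: dict  # class name -> RbfScorer (binary: one entry, the positive class)
    classes: list[str]
    positive_class: str
    decision_threshold: float = 0.5
    fingerprint: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.decision_threshold <= 1.0):
            raise DataError("decision_threshold must be in [0,1]")

    # -- prediction -------------------------------------------------------
    def _features(self, matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Apply the stored log2/Z-score chain; return (X, ood_flags)."""
        if matrix.scale == "fpkm":
            matrix = log2_transform(matrix)
        elif matrix.scale != "log2":
            raise DataError("predict expects an fpkm- or log2-scale matrix")
        aligned, missing = align_features(matrix, self.panel.transcript_ids)
        if missing:
            raise DataError(
                f"{len(missing)} panel features missing from input "
                f"(e.g. {missing[:3]}); align features and retrain on the "
                "intersection, or supply a matrix covering the panel"
            )
        # stats rows follow the panel; rename aligned rows to panel order
        aligned = ExpressionMatrix(
            aligned.data.set_axis(self.panel.transcript_ids, axis=0), "log2"
        )
        z = apply_zscore(aligned, self.stats)
        X = z.values_by_sample().to_numpy()
        ood = np.abs(X).max(axis=1) > 6.0
        return X, ood

    def predict_scores(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Per-sample calibrated scores (one column per class scorer) + OOD flag."""
        X, ood = self._features(matrix)
        out = pd.DataFrame(index=matrix.sample_ids)
        for cls_name, scorer in self.scorers.items():
            out[cls_name] = scorer.probability(X)
        out["ood_flag"] = ood
        return out

    def predict(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Class calls: binary uses the decision threshold (inclusive >=),
        multiclass the argmax of per-class scores."""
        scores = self.predict_scores(matrix)
        if self.kind == "binary":
            pos = scores[self.positive_class] >= self.decision_threshold
            neg_class = next(c for c in self.classes if c != self.positive_class)
            call = np.where(pos, self.positive_class, neg_class)
        else:
            call = scores[self.classes].idxmax(axis=1).to_numpy()
        out = scores.copy()
        out["call"] = call
        return out

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.panel.write(directory / "panel.tsv")
        self.stats.write(directory / "stats.tsv")
        for cls_name, scorer in self.scorers.items():
            with open(directory / f"scorer_{cls_name}.json", "w") as fh:
                json.dump(scorer.to_dict(), fh)
        manifest = {
            "schema": ARCHIVE_SCHEMA,
            "kind": self.kind,
            "classes": self.classes,
            "positive_class": self.positive_class,
            "decision_threshold": self.decision_threshold,
            "fingerprint": self.fingerprint,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedStageModel":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        if manifest.get("schema") != ARCHIVE_SCHEMA:
            raise DataError(f"unsupported model archive schema: {manifest.get('schema')}")
        panel = FeaturePanel.read(directory / "panel.tsv")
        stats = NormalizationStats.read(directory / "stats.tsv")
        scorers = {}
        for cls_name in (
            manifest["classes"] if manifest["kind"] == "multiclass"
            else [manifest["positive_class"]]
        ):
            with open(directory / f"scorer_{cls_name}.json") as fh:
                scorers[cls_name] = RbfScorer.from_dict(json.load(fh))
        return cls(
            kind=manifest["kind"],
            panel=panel,
            stats=stats,
            scorers=scorers,
            classes=manifest["classes"],
            positive_class=manifest["positive_class"],
            decision_threshold=manifest["decision_threshold"],
            fingerprint=manifest.get("fingerprint", {}),
        )


def _encoded(matrix: ExpressionMatrix, labels: SampleLabels):
    y = labels.class_array(matrix.sample_ids)
    X = matrix.values_by_sample().to_numpy()
    return X, y


def grid_search_cv(
    matrix: ExpressionMatrix, labels: SampleLabels, grid: GridSpec
) -> tuple[float, float, pd.DataFrame]:
    """Stratified k-fold CV accuracy per (gamma, cost) cell; argmax returned.

    Ties resolve to the smallest cost, then the smallest gamma.
    """
    X, y = _encoded(matrix, labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < grid.folds:
        raise DataError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} samples, fewer "
            f"than {grid.folds} folds; use stratification-compatible fold counts"
        )
    skf = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=grid.seed)
    splits = list(skf.split(X, y))
    rows = []
    best = (-1.0, None, None)
    for cost in sorted(grid.cost_values):
        for gamma in sorted(grid.gamma_values):
            correct = 0
            for tr, te in splits:
                clf = SVC(kernel="rbf", C=cost, gamma=gamma)
                clf.fit(X[tr], y[tr])
                correct += int((clf.predict(X[te]) == y[te]).sum())
            acc = correct / len(y)
            rows.append({"gamma": gamma, "cost": cost, "cv_accuracy": acc})
            if acc > best[0]:
                best = (acc, gamma, cost)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


def choose_decision_threshold(scores, labels) -> float:
    """Operating point with minimum |recall - specificity|, ties by maximum
    accuracy then smallest threshold.

    Candidate thresholds are the unique scores.  Degenerate (constant)
    scores return 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise DataError("choose_decision_threshold: both classes must be present")
    candidates = np.unique(scores)
    if len(candidates) == 1:
        warnings.warn("constant scores: decision threshold defaulting to 0.5")
        return 0.5
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    best = None
    for t in candidates:  # ascending, so the smallest threshold wins ties
        pred = scores >= t
        recall = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        acc = ((pred == (y == 1)).sum()) / len(y)
        key = (abs(recall - spec), -acc)
        if best is None or key < best[0]:
            best = (key, float(t))
    return best[1]


def train_binary(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    panel: FeaturePanel,
    grid: GridSpec | None = None,
    positive_class: str = "early",
    tune_threshold: bool = False,
) -> TrainedStageModel:
    """Fit the full deployable chain for a two-class task.

    The input matrix is on the fpkm or log2 scale; normalization statistics
    are fitted here, on the training samples, and frozen into the model.
    """
    grid = grid or GridSpec()
    if matrix.scale == "fpkm":
        matrix = log2_transform(matrix)
    missing = [t for t in panel.transcript_ids if t not in set(matrix.transcript_ids)]
    if missing:
        raise DataError(f"panel features absent from training matrix: {missing[:5]}")
    sub = matrix.subset_transcripts(panel.transcript_ids)
    stats = fit_zscore(sub)
    if stats.zero_sd:
        raise DataError(f"panel contains zero-variance transcripts: {stats.zero_sd[:5]}")
    z = apply_zscore(sub, stats)
    y_cls = labels.class_array(z.sample_ids)
    classes = sorted(set(y_cls))
    if len(classes) != 2:
        raise DataError(f"train_binary needs exactly 2 classes, got {classes}")
    if positive_class not in classes:
        raise DataError(f"positive class {positive_class!r} not in labels {classes}")
    gamma, cost, table = grid_search_cv(z, labels, grid)
    X = z.values_by_sample().to_numpy()
    y = (y_cls == positive_class).astype(int)
    scorer = _fit_scorer(X, y, gamma, cost, grid.seed)
    model = TrainedStageModel(
        kind="binary",
        panel=panel,
        stats=stats,
        scorers={positive_class: scorer},
        classes=classes,
        positive_class=positive_class,
        fingerprint={
            "gamma": gamma, "cost": cost, "folds": grid.folds, "seed": grid.seed,
            "cv_accuracy": float(table["cv_accuracy"].max()), "n_train": len(y),
        },
    )
    if tune_threshold:
        train_scores = scorer.probability(X)
        model.decision_threshold = choose_decision_threshold(train_scores, y)
    return model


def train_multiclass_ovr(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    panel: FeaturePanel,
    grid: GridSpec | None = None,
    classes: tuple[str, ...] = ("normal", "early", "late"),
) -> TrainedStageModel:
    """One-vs-rest: one calibrated binary scorer per class, argmax prediction."""
    grid = grid or GridSpec()
    if matrix.scale == "fpkm":
        matrix = log2_transform(matrix)
    sub = matrix.subset_transcripts(panel.transcript_ids)
    stats = fit_zscore(sub)
    if stats.zero_sd:
        raise DataError(f"panel contains zero-variance transcripts: {stats.zero_sd[:5]}")
    z = apply_zscore(sub, stats)
    y_cls = labels.class_array(z.sample_ids)
    present = [c for c in classes if c in set(y_cls)]
    if len(present) < 2:
        raise DataError("train_multiclass_ovr needs >= 2 classes present")
    counts = {c: int((y_cls == c).sum()) for c in present}
    small = [c for c, n in counts.items() if n < grid.folds]
    if small:
        raise DataError(f"classes with fewer samples than folds: {small}")
    gamma, cost, table = grid_search_cv(z, labels, grid)
    X = z.values_by_sample().to_numpy()
    scorers = {}
    for c in present:
        y = (y_cls == c).astype(int)
        scorers[c] = _fit_scorer(X, y, gamma, cost, grid.seed)
    return TrainedStageModel(
        kind="multiclass",
        panel=panel,
        stats=stats,
        scorers=scorers,
        classes=present,
        positive_class=present[0],
        fingerprint={
            "gamma": gamma, "cost": cost, "folds": grid.folds, "seed": grid.seed,
            "cv_accuracy": float(table["cv_accuracy"].max()), "n_train": len(y_cls),
        },
    )


def predict_scores(model: TrainedStageModel, matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample probability of the positive class (binary models)."""
    if model.kind != "binary":
        raise DataError("predict_scores is for binary models; use model.predict_scores")
    return model.predict_scores(matrix)[model.positive_class]


def cross_validate(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    panel: FeaturePanel,
    gamma: float = 0.01,
    cost: float = 1.0,
    folds: int | None = 10,
    seed: int = 0,
    positive_class: str = "early",
) -> tuple[list[MetricReport], MetricReport]:
    """Stratified k-fold (or leave-one-out with ``folds=None``) evaluation.

    Each sample is tested exactly once; the pooled confusion across folds
    is reported alongside the per-fold reports (per-fold metrics are
    undefined-heavy under LOO, where test folds are singletons).
    """
    if matrix.scale == "fpkm":
        matrix = log2_transform(matrix)
    sub = matrix.subset_transcripts(panel.transcript_ids)
    y_cls = labels.class_array(sub.sample_ids)
    y = (y_cls == positive_class).astype(int)
    X_log = sub.values_by_sample().to_numpy()
    n = len(y)
    if folds is None:
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        if folds > n:
            raise DataError(f"folds={folds} exceeds sample count {n}")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X_log, y))
    fold_reports = []
    pooled_true = np.empty(n, dtype=int)
    pooled_pred = np.empty(n, dtype=int)
    for tr, te in splits:
        mu = X_log[tr].mean(axis=0)
        sd = X_log[tr].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # a fold-constant feature carries no information
        Xtr = (X_log[tr] - mu) / sd
        Xte = (X_log[te] - mu) / sd
        clf = SVC(kernel="rbf", C=cost, gamma=gamma)
        clf.fit(Xtr, y[tr])
        pred = clf.predict(Xte)
        pooled_true[te] = y[te]
        pooled_pred[te] = pred
        if len(te) > 1:
            fold_reports.append(compute_metrics(confusion_counts(y[te], pred, positive=1)))
    pooled = compute_metrics(confusion_counts(pooled_true, pooled_pred, positive=1))
    return fold_reports, pooled
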