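"""Multivariate feature selection over expression panels.

Four selectors with one output type:

* FCBF — the fast correlation-based filter: rank features by symmetrical
  uncertainty (SU) with the class after supervised MDL discretization, then
  prune any feature predominated by an already-kept one.
* ANOVA-F — top-k by the one-way F statistic.
* L1 linear-margin — features with non-zero weight in an L1-penalized
  squared-hinge linear classifier.
* Stochastic subset search — a seeded genetic bit-mask search maximizing
  10-fold cross-validated MCC of a margin classifier (a generic stand-in
  for wrapper searches with the same encoding and objective).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from .evaluate import confusion_counts, matthews_corrcoef
from .expression_io import DataError, ExpressionMatrix, SampleLabels

__all__ = [
    "FeaturePanel",
    "mdl_discretize",
    "symmetrical_uncertainty",
    "fcbf_select",
    "anova_f_select",
    "l1_linear_select",
    "l1_panel_size_search",
    "subset_search_select",
]


@dataclass
class FeaturePanel:
    """An ordered set of selected transcripts with selection provenance."""

    transcript_ids: list[str]
    method: str
    parameters: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    source_fingerprint: str = ""

    def __post_init__(self) -> None:
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise DataError("duplicate transcript IDs in feature panel")

    def __len__(self) -> int:
        return len(self.transcript_ids)

    def __iter__(self):
        return iter(self.transcript_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.transcript_ids) + 1),
                "transcript_id": self.transcript_ids,
                "score": [self.scores.get(t, np.nan) for t in self.transcript_ids],
                "method": self.method,
                "parameters": json.dumps(self.parameters, sort_keys=True),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "FeaturePanel":
        df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
        params = json.loads(df["parameters"].iloc[0]) if len(df) else {}
        method = df["method"].iloc[0] if len(df) else ""
        return cls(
            transcript_ids=df["transcript_id"].tolist(),
            method=method,
            parameters=params,
            scores={t: s for t, s in zip(df["transcript_id"], df["score"]) if np.isfinite(s)},
        )


# ---------------------------------------------------------------------------
# Supervised discretization (Fayyad-Irani MDL stopping rule)

def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mdl_discretize(values, labels) -> list[float]:
    """Recursive entropy-minimizing binary splits with the MDL stopping rule.

    Candidate cut points are midpoints between adjacent distinct sorted
    values; a split is accepted iff its information gain exceeds
    (log2(n-1) + log2(3^k - 2) - k*E + k1*E1 + k2*E2) / n, where k, k1, k2
    are the class counts present in the node and its children and E the
    corresponding entropies.  Returns a possibly empty list of cuts (empty
    means the feature collapses to a single bin).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise DataError("mdl_discretize: values and labels differ in length")
    order = np.argsort(values, kind="mergesort")
    v, y = values[order], labels[order]
    cuts: list[float] = []
    _mdl_split(v, y, cuts)
    return sorted(cuts)


def _mdl_split(v: np.ndarray, y: np.ndarray, cuts: list[float]) -> None:
    n = len(v)
    if n < 2:
        return
    e_parent = _entropy(y)
    if e_parent == 0.0:
        return
    best_gain, best_idx = -1.0, -1
    best_parts = None
    # boundaries between distinct adjacent values
    for i in range(1, n):
        if v[i] == v[i - 1]:
            continue
        e1 = _entropy(y[:i])
        e2 = _entropy(y[i:])
        gain = e_parent - (i * e1 + (n - i) * e2) / n
        if gain > best_gain:
            best_gain, best_idx = gain, i
            best_parts = (e1, e2)
    if best_idx < 0:
        return
    e1, e2 = best_parts
    k = len(np.unique(y))
    k1 = len(np.unique(y[:best_idx]))
    k2 = len(np.unique(y[best_idx:]))
    threshold = (
        math.log2(n - 1) + math.log2(3**k - 2) - k * e_parent + k1 * e1 + k2 * e2
    ) / n
    if best_gain <= threshold:
        return
    cut = (v[best_idx - 1] + v[best_idx]) / 2.0
    cuts.append(float(cut))
    _mdl_split(v[:best_idx], y[:best_idx], cuts)
    _mdl_split(v[best_idx:], y[best_idx:], cuts)


# ---------------------------------------------------------------------------
# Symmetrical uncertainty and FCBF

def symmetrical_uncertainty(x, y) -> float:
    """SU(x,y) = 2 I(x;y) / (H(x) + H(y)) with base-2 entropies; 0 when both
    entropies vanish."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise DataError("symmetrical_uncertainty: length mismatch")
    hx = _entropy(x)
    hy = _entropy(y)
    if hx + hy == 0.0:
        return 0.0
    # joint entropy from empirical joint frequencies
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy().ravel()
    joint = joint[joint > 0]
    p = joint / joint.sum()
    hxy = float(-(p * np.log2(p)).sum())
    mi = hx + hy - hxy
    su = 2.0 * mi / (hx + hy)
    return float(min(max(su, 0.0), 1.0))


def _discretize_matrix(matrix: ExpressionMatrix, y: np.ndarray) -> dict[str, np.ndarray]:
    """Bin each transcript by its MDL cuts; single-bin features are dropped."""
    out: dict[str, np.ndarray] = {}
    X = matrix.data.to_numpy(dtype=float)
    for i, tid in enumerate(matrix.transcript_ids):
        cuts = mdl_discretize(X[i], y)
        if cuts:
            out[tid] = np.searchsorted(cuts, X[i], side="left")
    return out


def fcbf_select(
    matrix: ExpressionMatrix, labels: SampleLabels,
    positive_class: str = "early", negative_class: str = "late",
    su_threshold: float = 0.0,
) -> FeaturePanel:
    """Fast correlation-based filter on MDL-discretized expression.

    Features are ranked by SU with the class (descending, ties by ID); a
    feature is kept unless some already-kept feature predominates it, i.e.
    has feature-feature SU >= its class SU.  Only features with class SU >=
    ``su_threshold`` (and a non-trivial discretization) are considered.
    """
    if not (0.0 <= su_threshold <= 1.0):
        raise DataError(f"su_threshold must be in [0,1], got {su_threshold}")
    cls = labels.class_array(matrix.sample_ids)
    mask = (cls == positive_class) | (cls == negative_class)
    sub = matrix.subset_samples([s for s, m in zip(matrix.sample_ids, mask) if m])
    y = (cls[mask] == positive_class).astype(int)
    disc = _discretize_matrix(sub, y)
    class_su = {tid: symmetrical_uncertainty(xd, y) for tid, xd in disc.items()}
    candidates = [t for t in class_su if class_su[t] >= su_threshold and class_su[t] > 0]
    candidates.sort(key=lambda t: (-class_su[t], t))
    kept: list[str] = []
    for tid in candidates:
        predominated = any(
            symmetrical_uncertainty(disc[tid], disc[kj]) >= class_su[tid] for kj in kept
        )
        if not predominated:
            kept.append(tid)
    return FeaturePanel(
        transcript_ids=kept,
        method="fcbf",
        parameters={"su_threshold": su_threshold},
        scores={t: class_su[t] for t in kept},
    )


# ---------------------------------------------------------------------------
# ANOVA-F and L1 selection

def anova_f_select(matrix: ExpressionMatrix, labels: SampleLabels, k: int) -> FeaturePanel:
    """Top-k transcripts by one-way ANOVA F statistic (any number of classes)."""
    if k < 1:
        raise DataError("anova_f_select: k must be >= 1")
    if k > matrix.n_transcripts:
        raise DataError(
            f"anova_f_select: k={k} exceeds feature count {matrix.n_transcripts}"
        )
    y = labels.class_array(matrix.sample_ids)
    if len(np.unique(y)) < 2:
        raise DataError("anova_f_select needs >= 2 classes")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Features .* are constant")
        F, _ = f_classif(matrix.values_by_sample().to_numpy(), y)
    F = np.nan_to_num(F, nan=0.0)  # constant features carry no signal; +inf (zero within-SS) ranks first
    order = np.argsort(-F, kind="mergesort")[:k]
    ids = [matrix.transcript_ids[i] for i in order]
    return FeaturePanel(
        transcript_ids=ids,
        method="anova_f",
        parameters={"k": k},
        scores={matrix.transcript_ids[i]: float(F[i]) for i in order},
    )


def l1_linear_select(
    matrix: ExpressionMatrix, labels: SampleLabels, penalty_strength: float = 1.0,
    positive_class: str = "early",
) -> FeaturePanel:
    """Features with non-zero weight under an L1-penalized squared-hinge
    linear margin classifier (objective: sum of squared hinge losses +
    penalty_strength * ||w||_1), ordered by |w| descending.

    Expects Z-scored input so the penalty treats features comparably.
    """
    if matrix.scale != "zscore":
        raise DataError("l1_linear_select expects Z-scored input")
    y_cls = labels.class_array(matrix.sample_ids)
    if len(np.unique(y_cls)) < 2:
        raise DataError("l1_linear_select: need two classes")
    y = (y_cls == positive_class).astype(int)
    clf = LinearSVC(
        penalty="l1", loss="squared_hinge", dual=False,
        C=1.0 / penalty_strength, max_iter=20000, tol=1e-5,
        random_state=0,  # liblinear's internal shuffling must not follow the global RNG
    )
    clf.fit(matrix.values_by_sample().to_numpy(), y)
    w = clf.coef_.ravel()
    nz = np.abs(w) > 1e-8
    order = np.argsort(-np.abs(w), kind="mergesort")
    ids = [matrix.transcript_ids[i] for i in order if nz[i]]
    return FeaturePanel(
        transcript_ids=ids,
        method="l1_linear",
        parameters={"penalty_strength": penalty_strength},
        scores={matrix.transcript_ids[i]: float(abs(w[i])) for i in order if nz[i]},
    )


def l1_panel_size_search(
    matrix: ExpressionMatrix, labels: SampleLabels, target_size: int,
    positive_class: str = "early", max_iter: int = 30,
) -> FeaturePanel:
    """Bisect the L1 penalty to reach (approximately) a requested panel size."""
    lo, hi = 1e-4, 1e4  # penalty strengths bracketing dense..empty panels
    best = None
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        panel = l1_linear_select(matrix, labels, mid, positive_class)
        if best is None or abs(len(panel) - target_size) < abs(len(best) - target_size):
            best = panel
        if len(panel) == target_size:
            return panel
        if len(panel) > target_size:
            lo = mid  # stronger penalty needed
        else:
            hi = mid
    return best


# ---------------------------------------------------------------------------
# Stochastic subset search (bit-mask genetic search, CV-MCC objective)

def _cv_mcc(X: np.ndarray, y: np.ndarray, mask: np.ndarray, folds: int, seed: int) -> float:
    if not mask.any():
        return -1.0
    Xm = X[:, mask]
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise DataError("subset search: smallest class too small for CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for tr, te in skf.split(Xm, y):
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
        clf.fit(Xm[tr], y[tr])
        pred[te] = clf.predict(Xm[te])
    return matthews_corrcoef(confusion_counts(y, pred, positive=1))


def subset_search_select(
    matrix: ExpressionMatrix, labels: SampleLabels, pool: FeaturePanel,
    iterations: int = 50, seed: int = 0,
    positive_class: str = "early", folds: int = 10,
    population: int = 12, mutation_rate: float = 0.1,
) -> tuple[FeaturePanel, list[float]]:
    """Seeded genetic search over feature bit-masks maximizing CV MCC.

    Candidate subsets are encoded as binary vectors over the pool (at most
    100 features).  Each generation keeps the elite half, refills by
    uniform crossover of elite parents plus bit-flip mutation, and scores
    fitness as the pooled 10-fold cross-validated MCC of an RBF margin
    classifier on the masked features.  Returns the best panel and the
    per-generation best-fitness trace.
    """
    if len(pool) == 0:
        raise DataError("subset_search_select: empty pool")
    if len(pool) > 100:
        raise DataError("subset_search_select: pool size limited to 100 features")
    if iterations < 1:
        raise DataError("subset_search_select: iterations must be >= 1")
    sub = matrix.subset_transcripts(list(pool))
    y_cls = labels.class_array(sub.sample_ids)
    y = (y_cls == positive_class).astype(int)
    X = sub.values_by_sample().to_numpy()
    rng = np.random.default_rng(seed)
    n_feat = len(pool)
    pop = rng.random((population, n_feat)) < 0.5
    for i in range(population):
        if not pop[i].any():
            pop[i, rng.integers(n_feat)] = True
    fitness = np.array([_cv_mcc(X, y, m, folds, seed) for m in pop])
    trace = [float(fitness.max())]
    for _ in range(iterations - 1):
        elite_idx = np.argsort(-fitness, kind="mergesort")[: max(2, population // 2)]
        elite = pop[elite_idx]
        children = []
        while len(children) < population - len(elite):
            pa, pb = rng.choice(len(elite), size=2, replace=False)
            take = rng.random(n_feat) < 0.5
            child = np.where(take, elite[pa], elite[pb])
            flip = rng.random(n_feat) < mutation_rate
            child = child ^ flip
            if not child.any():
                child[rng.integers(n_feat)] = True
            children.append(child)
        pop = np.vstack([elite, np.array(children)])
        fitness = np.array([_cv_mcc(X, y, m, folds, seed) for m in pop])
        trace.append(float(fitness.max()))
    best = pop[int(np.argmax(fitness))]
    ids = [tid for tid, b in zip(pool, best) if b]
    panel = FeaturePanel(
        transcript_ids=ids,
        method="subset_search",
        parameters={
            "iterations": iterations, "seed": seed, "folds": folds,
            "population": population, "mutation_rate": mutation_rate,
            "fitness": float(fitness.max()),
        },
        scores={t: float(fitness.max()) for t in ids},
    )
    return panel, trace
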