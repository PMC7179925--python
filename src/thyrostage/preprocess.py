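"""Expression transforms: log2(FPKM+1), variance filtering, training-set
Z-scoring, and feature-specific quantile normalization against a reference
cohort.

The pipeline order is fixed: log2 transform, then variance filter, then
Z-score.  Variance and standard deviation use the n-1 (sample) denominator
throughout, so the conventional 0.25 (stage task) and 0.02 (cancer/normal
task) cutoffs are interpretable as sample variances of log2(FPKM+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import DataError, ExpressionMatrix

__all__ = [
    "NormalizationStats",
    "VarianceFilterReport",
    "log2_transform",
    "variance_filter",
    "fit_zscore",
    "apply_zscore",
    "quantile_normalize_to_reference",
    "align_features",
    "strip_version",
]


def strip_version(transcript_id: str) -> str:
    """Drop an Ensembl-style version suffix (ENST00000123456.7 -> ...456).

    Annotation versions drift between cohorts; matching is done on the
    unversioned ID while the original ID is retained in outputs.
    """
    base, dot, suffix = transcript_id.rpartition(".")
    if dot and suffix.isdigit():
        return base
    return transcript_id


@dataclass
class NormalizationStats:
    """Per-transcript training mean and standard deviation on the log2 scale.

    ``zero_sd`` lists transcripts whose training sd is 0; these are flagged
    here and rejected only if Z-scoring is actually attempted on them.
    """

    mean: pd.Series
    sd: pd.Series
    zero_sd: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise DataError("mean and sd indexed by different transcripts")
        if (self.sd < 0).any():
            raise DataError("negative standard deviation in normalization stats")

    @property
    def transcript_ids(self) -> list[str]:
        return self.mean.index.tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd}).rename_axis("transcript_id")

    def write(self, path: str | Path) -> None:
        # %.17g round-trips float64 exactly through text
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read(cls, path: str | Path) -> "NormalizationStats":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        zero = df.index[df["sd"] == 0].tolist()
        return cls(df["mean"], df["sd"], zero)


@dataclass
class VarianceFilterReport:
    kept: int
    removed: int
    min_variance: float


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """x <- log2(x + 1), entrywise; FPKM scale in, log2 scale out."""
    if matrix.scale != "fpkm":
        raise DataError(f"log2_transform expects scale='fpkm', got {matrix.scale!r}")
    return ExpressionMatrix(np.log2(matrix.data + 1.0), scale="log2")


def variance_filter(
    matrix: ExpressionMatrix, min_variance: float = 0.25
) -> tuple[ExpressionMatrix, VarianceFilterReport]:
    """Drop transcripts with sample variance below ``min_variance``.

    Applied on the log2 scale, after the log transform and before Z-scoring.
    """
    if min_variance < 0:
        raise DataError(f"min_variance must be >= 0, got {min_variance}")
    if matrix.scale != "log2":
        raise DataError(f"variance_filter expects scale='log2', got {matrix.scale!r}")
    var = matrix.data.var(axis=1, ddof=1)
    keep = var[var >= min_variance].index
    out = ExpressionMatrix(matrix.data.loc[keep], matrix.scale)
    return out, VarianceFilterReport(
        kept=len(keep), removed=matrix.n_transcripts - len(keep), min_variance=min_variance
    )


def fit_zscore(matrix: ExpressionMatrix) -> NormalizationStats:
    """Record per-transcript mean and sd (ddof=1) of the training matrix."""
    if matrix.scale != "log2":
        raise DataError(f"fit_zscore expects scale='log2', got {matrix.scale!r}")
    if matrix.n_samples < 2:
        raise DataError("fit_zscore needs at least 2 samples")
    mean = matrix.data.mean(axis=1)
    sd = matrix.data.std(axis=1, ddof=1)
    zero = sd.index[sd == 0].tolist()
    return NormalizationStats(mean, sd, zero)


def apply_zscore(matrix: ExpressionMatrix, stats: NormalizationStats) -> ExpressionMatrix:
    """(x - mu) / sigma using the *training* statistics, never the target's own."""
    if matrix.scale != "log2":
        raise DataError(f"apply_zscore expects scale='log2', got {matrix.scale!r}")
    missing = [t for t in matrix.transcript_ids if t not in stats.mean.index]
    if missing:
        raise DataError(f"transcripts missing from normalization stats: {missing[:5]}")
    zero = [t for t in matrix.transcript_ids if t in set(stats.zero_sd)]
    if zero:
        raise DataError(
            f"cannot Z-score zero-variance transcripts: {zero[:5]}; "
            "filter them out before normalization"
        )
    mu = stats.mean.loc[matrix.transcript_ids]
    sd = stats.sd.loc[matrix.transcript_ids]
    z = matrix.data.sub(mu, axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, scale="zscore")


def quantile_normalize_to_reference(
    target: ExpressionMatrix, reference: ExpressionMatrix
) -> ExpressionMatrix:
    """Map each transcript's target distribution onto the reference's.

    Feature-specific quantile normalization for cross-platform validation:
    per transcript, the rank-r target value (rank scaled to [0,1] as
    r/(n_target-1)) is replaced by the reference's empirical quantile at
    that position, linearly interpolated when sample counts differ.  Tied
    target values share the mean of their mapped values, so the map is
    deterministic and order-preserving; with equal sample counts the output
    multiset equals the reference multiset exactly.
    """
    if target.scale != reference.scale:
        raise DataError("target and reference must share a scale")
    shared = [t for t in target.transcript_ids if t in set(reference.transcript_ids)]
    if not shared:
        raise DataError("no shared transcripts between target and reference")
    if reference.n_samples < 2:
        raise DataError("reference needs at least 2 samples per transcript")
    n_t = target.n_samples
    n_r = reference.n_samples
    ref_positions = np.linspace(0.0, 1.0, n_r)
    out = {}
    for tid in shared:
        tv = target.data.loc[tid].to_numpy(dtype=float)
        rv = np.sort(reference.data.loc[tid].to_numpy(dtype=float))
        if n_t == 1:
            mapped_sorted = np.array([np.interp(0.5, ref_positions, rv)])
        else:
            positions = np.arange(n_t) / (n_t - 1)
            mapped_sorted = np.interp(positions, ref_positions, rv)
        order = np.argsort(tv, kind="stable")
        mapped = np.empty(n_t)
        mapped[order] = mapped_sorted
        # ties share the mean of their mapped values
        uniq, inverse = np.unique(tv, return_inverse=True)
        if len(uniq) < n_t:
            sums = np.bincount(inverse, weights=mapped)
            counts = np.bincount(inverse)
            mapped = (sums / counts)[inverse]
        out[tid] = mapped
    df = pd.DataFrame(out, index=target.sample_ids).T
    df.index.name = target.data.index.name
    return ExpressionMatrix(df, scale=target.scale)


def align_features(
    matrix: ExpressionMatrix, panel_ids: list[str], match_versions: bool = False
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict and reorder rows to a feature panel; report what is missing.

    With ``match_versions=False`` (default) Ensembl version suffixes are
    ignored when matching, so a panel built on one annotation release can be
    applied to a cohort quantified on another.  The caller decides whether a
    non-empty ``missing`` list warrants retraining on the intersection.
    """
    if match_versions:
        lookup = {t: t for t in matrix.transcript_ids}
        wanted = list(panel_ids)
    else:
        lookup = {}
        for t in matrix.transcript_ids:
            lookup.setdefault(strip_version(t), t)
        wanted = [strip_version(p) for p in panel_ids]
    found = [lookup[w] for w in wanted if w in lookup]
    missing = [p for p, w in zip(panel_ids, wanted) if w not in lookup]
    if not found:
        raise DataError("no panel transcripts present in the matrix")
    return matrix.subset_transcripts(found), missing
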