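"""Expression-matrix, stage-label and annotation I/O, plus the stratified split.

The on-disk dialect is the GDC HTSeq-FPKM convention: transcripts as rows
(first column ``transcript_id``), samples as columns, decimal-point numerics,
tab- or comma-separated.  Stage labels are a two-column table (sample_id,
stage) with stage spelled as roman numerals, arabic numerals, ``stage N``
prefixes (case-insensitive) or ``normal``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleLabels",
    "TranscriptAnnotation",
    "BiotypeFilterReport",
    "read_fpkm_matrix",
    "write_matrix",
    "read_stage_labels",
    "read_annotation",
    "filter_by_biotype",
    "stratified_split",
    "parse_stage",
]

#: Valid values for :attr:`ExpressionMatrix.scale`.
SCALES = ("fpkm", "log2", "zscore")

#: Merged binary endpoint: AJCC stages I-II pooled vs III-IV pooled.
STAGE_TO_CLASS = {"I": "early", "II": "early", "III": "late", "IV": "late",
                  "normal": "normal"}

_ROMAN = {"i": "I", "ii": "II", "iii": "III", "iv": "IV",
          "1": "I", "2": "II", "3": "III", "4": "IV"}


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A transcripts-by-samples expression matrix with a scale tag.

    ``data`` is a :class:`pandas.DataFrame` indexed by transcript ID with
    sample IDs as columns.  ``scale`` records where the values sit in the
    log2(FPKM+1) / Z-score transform chain.
    """

    data: pd.DataFrame
    scale: str = "fpkm"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise DataError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate transcript IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise DataError("expression matrix contains missing or non-finite entries")
        if self.scale == "fpkm" and values.size and (values < 0).any():
            raise DataError("negative FPKM value in expression matrix")

    @property
    def transcript_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_transcripts(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values_by_sample(self) -> pd.DataFrame:
        """Samples-as-rows orientation (the classifier-facing view)."""
        return self.data.T

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale)

    def subset_transcripts(self, transcript_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(transcript_ids)], self.scale)


@dataclass
class SampleLabels:
    """Per-sample class labels (normal / early / late), with raw stage kept.

    ``classes`` maps sample_id -> merged class; ``raw_stage`` retains the
    original stage string (I-IV or normal) when it was available.
    """

    classes: dict[str, str]
    raw_stage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in ("normal", "early", "late")}
        if bad:
            raise DataError(f"unknown class labels: {sorted(bad)}")
        for sid, stage in self.raw_stage.items():
            expect = STAGE_TO_CLASS.get(stage)
            if expect is None:
                raise DataError(f"unknown raw stage {stage!r} for sample {sid!r}")
            if self.classes.get(sid) != expect:
                raise DataError(
                    f"sample {sid!r}: raw stage {stage!r} implies class {expect!r}, "
                    f"got {self.classes.get(sid)!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.classes)

    def class_array(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.classes]
        if missing:
            raise DataError(f"unlabelled samples: {missing[:5]}")
        return np.array([self.classes[s] for s in sample_ids])

    def subset(self, sample_ids: list[str]) -> "SampleLabels":
        return SampleLabels(
            {s: self.classes[s] for s in sample_ids},
            {s: self.raw_stage[s] for s in sample_ids if s in self.raw_stage},
        )

    def stratum_key(self, sample_id: str) -> str:
        """Stratification key: the original stage when known, else the class."""
        return self.raw_stage.get(sample_id, self.classes[sample_id])


@dataclass
class TranscriptAnnotation:
    """transcript_id -> biotype lookup (protein_coding, lincRNA, ...)."""

    biotypes: dict[str, str]

    def get(self, transcript_id: str) -> str | None:
        return self.biotypes.get(transcript_id)


@dataclass
class BiotypeFilterReport:
    kept: int
    removed: int
    unannotated: list[str]


def parse_stage(text: str) -> str:
    """Normalize a clinical stage string to I/II/III/IV/normal.

    Accepts roman numerals, arabic numerals and ``stage N`` prefixes,
    case-insensitive.
    """
    s = str(text).strip().lower()
    if s == "normal":
        return "normal"
    s = re.sub(r"^stage\s*", "", s)
    if s in _ROMAN:
        return _ROMAN[s]
    raise DataError(f"unrecognized stage value: {text!r}")


def read_fpkm_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a transcripts-by-samples FPKM matrix from TSV or CSV.

    The first column holds transcript IDs; the header row holds sample IDs.
    Row and column order are preserved.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise DataError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        numeric = df.astype(float)  # numpy strtod: correctly-rounded, round-trip exact
    except ValueError:
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell at transcript {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        ) from None
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(f"missing value at transcript {df.index[r]!r}, sample {df.columns[c]!r}")
    return ExpressionMatrix(numeric.astype(float), scale="fpkm")


def write_matrix(matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a matrix in the dialect read by :func:`read_fpkm_matrix`."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise DataError(f"unknown dialect {dialect!r}")
    matrix.data.to_csv(path, sep=sep, index_label="transcript_id", float_format="%.17g")


def read_stage_labels(path: str | Path) -> SampleLabels:
    """Read a two-column (sample_id, stage) table and derive merged classes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError("labels table needs two columns: sample_id, stage")
    sample_col, stage_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dups = df.loc[df[sample_col].duplicated(), sample_col].tolist()
        raise DataError(f"duplicate sample IDs in labels: {dups}")
    raw = {str(r[sample_col]): parse_stage(r[stage_col]) for _, r in df.iterrows()}
    classes = {sid: STAGE_TO_CLASS[st] for sid, st in raw.items()}
    return SampleLabels(classes, raw)


def write_stage_labels(labels: SampleLabels, path: str | Path) -> None:
    rows = [(sid, labels.raw_stage.get(sid, labels.classes[sid]))
            for sid in labels.sample_ids]
    pd.DataFrame(rows, columns=["sample_id", "stage"]).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> TranscriptAnnotation:
    """Read a two-column (transcript_id, biotype) table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError("annotation table needs two columns: transcript_id, biotype")
    tcol, bcol = df.columns[:2]
    return TranscriptAnnotation(dict(zip(df[tcol].astype(str), df[bcol].astype(str))))


def filter_by_biotype(
    matrix: ExpressionMatrix,
    annotation: TranscriptAnnotation,
    biotypes: set[str],
) -> tuple[ExpressionMatrix, BiotypeFilterReport]:
    """Restrict rows to transcripts of the given biotypes, preserving order.

    Transcripts absent from the annotation are excluded and reported rather
    than silently dropped.
    """
    keep: list[str] = []
    unannotated: list[str] = []
    for tid in matrix.transcript_ids:
        bt = annotation.get(tid)
        if bt is None:
            unannotated.append(tid)
        elif bt in biotypes:
            keep.append(tid)
    report = BiotypeFilterReport(
        kept=len(keep),
        removed=matrix.n_transcripts - len(keep),
        unannotated=unannotated,
    )
    return ExpressionMatrix(matrix.data.loc[keep], matrix.scale), report


def stratified_split(
    matrix: ExpressionMatrix,
    labels: SampleLabels,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[tuple[ExpressionMatrix, SampleLabels], tuple[ExpressionMatrix, SampleLabels]]:
    """Split samples into training/validation per stratum.

    Stratification uses the original four-stage label when present (the
    merged early/late label otherwise).  Each stratum contributes exactly
    ``floor(train_fraction * n)`` training samples, drawn uniformly by
    ``seed``; with the study's stage strata 281/52/112/55 and 58 normals at
    0.8 this yields 265 early, 133 late and 46 normal training samples.
    """
    if not (0.0 < train_fraction < 1.0):
        raise DataError(f"train_fraction must be in (0,1), got {train_fraction}")
    sample_ids = matrix.sample_ids
    labels.class_array(sample_ids)  # validates coverage
    strata: dict[str, list[str]] = {}
    for sid in sample_ids:
        strata.setdefault(labels.stratum_key(sid), []).append(sid)
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for key in sorted(strata):
        members = strata[key]
        if not members:
            continue
        n_train = int(np.floor(train_fraction * len(members)))
        perm = rng.permutation(len(members))
        chosen = {members[i] for i in perm[:n_train]}
        train_ids.extend(s for s in members if s in chosen)
        val_ids.extend(s for s in members if s not in chosen)
    # preserve original sample order within each partition
    order = {s: i for i, s in enumerate(sample_ids)}
    train_ids.sort(key=order.get)
    val_ids.sort(key=order.get)
    return (
        (matrix.subset_samples(train_ids), labels.subset(train_ids)),
        (matrix.subset_samples(val_ids), labels.subset(val_ids)),
    )
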