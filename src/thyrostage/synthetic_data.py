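"""Synthetic FPKM expression cohorts with planted stage-informative markers.

The generator emulates the structure of a bulk RNA-seq tumor cohort with
matched adjacent-normal tissue: non-negative FPKM values, a lognormal
baseline per transcript, structural zeros (dropout), and a small planted
set of transcripts whose log2 expression shifts between classes.  Defaults
mirror the study conditions: class composition 333 early / 167 late / 58
normal, 2,000 transcripts (a desk-scale stand-in for the 60,483-feature
GDC matrices), 36 planted early/late markers at an effect of 1.5 within-
class standard deviations, plus a stronger tumor-vs-normal shift on the
same markers.  An "external cohort" generator reproduces the cross-platform
validation setting: a feature subset, a monotone per-feature platform
distortion, and a tiny 17 early / 3 late sample set.

Effects are additive on the log2 scale (multiplicative in FPKM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import DataError, ExpressionMatrix, SampleLabels

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_external_cohort",
    "generate_worked_example",
]


def _default_class_sizes() -> dict:
    return {"normal": 58, "early": 333, "late": 167}


def _default_external_sizes() -> dict:
    return {"early": 17, "late": 3}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study-shaped conditions."""

    n_transcripts: int = 2000
    n_informative: int = 36
    class_sizes: dict = field(default_factory=_default_class_sizes)
    #: early-vs-late mean shift of planted markers, in within-class sd units
    effect_size_sd: float = 1.5
    #: tumor-vs-normal shift of the same markers, in within-class sd units
    normal_effect_sd: float = 2.5
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 2.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.05
    external_overlap_fraction: float = 0.5
    external_class_sizes: dict = field(default_factory=_default_external_sizes)
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_transcripts:
            raise DataError("n_informative cannot exceed n_transcripts")
        if any(n < 0 for n in self.class_sizes.values()):
            raise DataError("class sizes must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise DataError("dropout_rate must be in [0,1)")
        if not (0.0 < self.external_overlap_fraction <= 1.0):
            raise DataError("external_overlap_fraction must be in (0,1]")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be > 0")


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    labels: SampleLabels
    #: planted markers: transcript_id -> {"direction", "effect_log2", "normal_effect_log2"}
    truth: dict

    def __post_init__(self) -> None:
        missing = set(self.truth) - set(self.matrix.transcript_ids)
        if missing:
            raise DataError(f"truth IDs not in matrix: {sorted(missing)[:5]}")


#: observed composition of the merged classes in the study cohort,
#: used to apportion raw stages within early (I:II = 281:52) and late
#: (III:IV = 112:55) so splits stratify on four stages as in real data
_STAGE_MIX = {"early": (("I", 281), ("II", 52)), "late": (("III", 112), ("IV", 55))}


def _sample_ids(class_sizes: dict) -> tuple[list[str], list[str], list[str]]:
    ids, classes, stages = [], [], []
    for cls in ("normal", "early", "late"):
        n = class_sizes.get(cls, 0)
        if cls == "normal":
            sub = ["normal"] * n
        else:
            (s1, w1), (s2, w2) = _STAGE_MIX[cls]
            n1 = int(round(n * w1 / (w1 + w2)))
            sub = [s1] * n1 + [s2] * (n - n1)
        for i in range(n):
            ids.append(f"{cls.upper()[:1]}{i:04d}")
            classes.append(cls)
            stages.append(sub[i])
    return ids, classes, stages


def generate_dataset(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Draw a labelled FPKM cohort with planted markers, fully seed-determined.

    Per transcript t: baseline level b_t ~ Normal(baseline_log_mean,
    baseline_log_sd) on the log2 scale.  Per sample s of class c:
    value = max(2^(b_t + shift_t(c) + Normal(0, noise_sd)) - 1, 0), where
    planted markers carry shift_t(late) - shift_t(early) = +-effect_size_sd
    * noise_sd (sign alternating by marker) and a tumor-vs-normal shift of
    +-normal_effect_sd * noise_sd; non-planted transcripts have no shift.
    Dropout zeros are applied last.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise DataError("pass either a config or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t = config.n_transcripts
    transcript_ids = [f"SYNT{i:08d}.1" for i in range(n_t)]
    sample_ids, classes, stages = _sample_ids(config.class_sizes)
    n_s = len(sample_ids)
    if n_s == 0:
        raise DataError("no samples requested")

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_t)
    informative_idx = rng.choice(n_t, size=config.n_informative, replace=False)
    el_effect = config.effect_size_sd * config.noise_sd
    cn_effect = config.normal_effect_sd * config.noise_sd

    shift = np.zeros((n_t, 3))  # columns: normal, early, late
    truth: dict = {}
    for j, idx in enumerate(sorted(informative_idx)):
        sign_el = 1.0 if j % 2 == 0 else -1.0  # alternate up/down in late
        sign_cn = 1.0 if (j // 2) % 2 == 0 else -1.0
        shift[idx, 1] = sign_cn * cn_effect            # early (tumor)
        shift[idx, 2] = sign_cn * cn_effect + sign_el * el_effect  # late
        truth[transcript_ids[idx]] = {
            "direction": "late_up" if sign_el > 0 else "late_down",
            "effect_log2": sign_el * el_effect,
            "normal_effect_log2": sign_cn * cn_effect,
        }

    class_col = np.array([{"normal": 0, "early": 1, "late": 2}[c] for c in classes])
    log_level = (
        baseline[:, None]
        + shift[:, class_col]
        + rng.normal(0.0, config.noise_sd, size=(n_t, n_s))
    )
    fpkm = np.maximum(np.exp2(log_level) - 1.0, 0.0)
    if config.dropout_rate > 0:
        fpkm[rng.random((n_t, n_s)) < config.dropout_rate] = 0.0

    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=transcript_ids, columns=sample_ids), scale="fpkm"
    )
    labels = SampleLabels(
        dict(zip(sample_ids, classes)), dict(zip(sample_ids, stages))
    )
    return SyntheticDataset(matrix=matrix, labels=labels, truth=truth)


def generate_external_cohort(
    dataset: SyntheticDataset, config: SimulationConfig
) -> SyntheticDataset:
    """An external-platform cohort sharing a feature subset with ``dataset``.

    Keeps ``external_overlap_fraction`` of the features (always including at
    least half of the planted truth set), applies a monotone per-feature
    distortion (scale + offset on the log2 level, emulating platform shift),
    and draws fresh samples with the external class sizes (default 17 early
    / 3 late).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    all_ids = dataset.matrix.transcript_ids
    truth_ids = [t for t in all_ids if t in dataset.truth]
    other_ids = [t for t in all_ids if t not in dataset.truth]
    n_keep = max(1, int(round(config.external_overlap_fraction * len(all_ids))))
    n_truth_keep = max(
        (len(truth_ids) + 1) // 2,
        min(len(truth_ids), int(round(config.external_overlap_fraction * len(truth_ids)))),
    )
    if truth_ids and n_truth_keep == 0:
        raise DataError("external overlap would exclude all planted features")
    kept_truth = sorted(rng.choice(truth_ids, size=n_truth_keep, replace=False).tolist()) \
        if truth_ids else []
    n_other = min(len(other_ids), max(0, n_keep - len(kept_truth)))
    kept_other = sorted(rng.choice(other_ids, size=n_other, replace=False).tolist())
    kept = [t for t in all_ids if t in set(kept_truth) | set(kept_other)]

    sample_ids, classes, _ = _sample_ids(
        {"normal": 0, **config.external_class_sizes}
    )
    sample_ids = [f"EXT_{s}" for s in sample_ids]
    # the emulated external cohort is stage 1 / stage 3 only
    stages = [{"early": "I", "late": "III"}[c] for c in classes]
    n_s = len(sample_ids)
    n_t = len(kept)

    # regenerate levels with the source dataset's planted effects
    base_lookup = {}
    src_log = np.log2(dataset.matrix.data + 1.0)
    for tid in kept:
        base_lookup[tid] = float(src_log.loc[tid].mean())
    scale = rng.uniform(0.8, 1.2, size=n_t)
    offset = rng.uniform(-1.0, 1.0, size=n_t)
    class_col = np.array([{"early": 1, "late": 2}[c] for c in classes])
    rows = np.empty((n_t, n_s))
    for i, tid in enumerate(kept):
        info = dataset.truth.get(tid)
        shifts = np.zeros(3)
        if info is not None:
            shifts[1] = 0.0
            shifts[2] = info["effect_log2"]
        level = (
            base_lookup[tid]
            + shifts[class_col]
            + rng.normal(0.0, config.noise_sd, size=n_s)
        )
        rows[i] = scale[i] * level + offset[i]  # monotone platform distortion
    fpkm = np.maximum(np.exp2(rows) - 1.0, 0.0)
    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=kept, columns=sample_ids), scale="fpkm"
    )
    labels = SampleLabels(
        dict(zip(sample_ids, classes)), dict(zip(sample_ids, stages))
    )
    truth = {t: dataset.truth[t] for t in kept_truth}
    return SyntheticDataset(matrix=matrix, labels=labels, truth=truth)


def generate_worked_example() -> SyntheticDataset:
    """A tiny fixed cohort (4 transcripts x 6 samples) with known optima.

    Transcript TA separates perfectly (threshold 3 on the raw values,
    point AUROC 1.0, higher in early); TB is imperfect (point AUROC 5/6);
    TC separates perfectly in the other direction; TD is constant
    (degenerate, point AUROC 0.5).  No RNG: regeneration is deterministic.
    """
    samples = ["E1", "E2", "E3", "L1", "L2", "L3"]
    data = pd.DataFrame(
        {
            "E1": [5.0, 3.0, 0.0, 2.0],
            "E2": [4.0, 3.0, 1.0, 2.0],
            "E3": [3.0, 2.0, 0.0, 2.0],
            "L1": [1.0, 2.0, 4.0, 2.0],
            "L2": [2.0, 1.0, 3.0, 2.0],
            "L3": [0.0, 1.0, 5.0, 2.0],
        },
        index=["TA", "TB", "TC", "TD"],
    )[samples]
    matrix = ExpressionMatrix(data, scale="fpkm")
    labels = SampleLabels(
        {"E1": "early", "E2": "early", "E3": "early",
         "L1": "late", "L2": "late", "L3": "late"},
        {"E1": "I", "E2": "I", "E3": "II", "L1": "III", "L2": "III", "L3": "IV"},
    )
    truth = {
        "TA": {"direction": "late_down", "effect_log2": -3.0, "normal_effect_log2": 0.0},
        "TC": {"direction": "late_up", "effect_log2": 4.0, "normal_effect_log2": 0.0},
    }
    return SyntheticDataset(matrix=matrix, labels=labels, truth=truth)
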