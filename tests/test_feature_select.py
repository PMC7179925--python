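import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import thyrostage as ts
from thyrostage.expression_io import DataError
from thyrostage.feature_select import mdl_discretize, symmetrical_uncertainty


def _dataset(rows: dict, classes: list, scale="log2"):
    samples = [f"S{i}" for i in range(len(classes))]
    df = pd.DataFrame(rows, index=samples).T.astype(float)
    matrix = ts.ExpressionMatrix(df, scale)
    labels = ts.SampleLabels(dict(zip(samples, classes)))
    return matrix, labels


class TestMdlDiscretize:
    def test_clean_split_accepted(self):
        cuts = mdl_discretize([1, 2, 3, 4], [0, 0, 1, 1])
        assert len(cuts) == 1
        assert 2 < cuts[0] <= 3

    def test_pure_labels_no_cuts(self):
        assert mdl_discretize([1, 2, 3, 4], [1, 1, 1, 1]) == []

    def test_interleaved_labels_rejected_by_mdl(self):
        # alternating labels: best gain stays below the MDL penalty at small n
        assert mdl_discretize([1, 2, 3, 4, 5, 6], [0, 1, 0, 1, 0, 1]) == []

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            mdl_discretize([1, 2], [0])

    def test_cuts_fall_between_observed_values(self, rng):
        vals = rng.normal(0, 1, 40)
        labs = (vals > 0).astype(int)
        cuts = mdl_discretize(vals, labs)
        assert cuts  # clean threshold structure must be found
        for c in cuts:
            assert vals.min() < c < vals.max()


class TestSymmetricalUncertainty:
    def test_identical_vectors(self):
        assert symmetrical_uncertainty([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_independent_balanced(self):
        x = [0, 0, 1, 1]
        y = [0, 1, 0, 1]
        assert symmetrical_uncertainty(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_joint(self):
        # joint counts {{2,0},{1,1}}: I = 0.8113 + 1 - 1.5 = 0.3113
        x = [0, 0, 1, 1]
        y = [0, 0, 1, 0]
        assert symmetrical_uncertainty(x, y) == pytest.approx(0.3437, abs=5e-4)

    def test_symmetry_and_range(self, rng):
        for _ in range(50):
            x = rng.integers(0, 3, 20)
            y = rng.integers(0, 2, 20)
            su_xy = symmetrical_uncertainty(x, y)
            su_yx = symmetrical_uncertainty(y, x)
            assert su_xy == pytest.approx(su_yx, abs=1e-12)
            assert 0.0 <= su_xy <= 1.0

    def test_both_constant(self):
        assert symmetrical_uncertainty([1, 1], [2, 2]) == 0.0


def reference_fcbf(features: dict, y, su_threshold=0.0):
    """Independent transcription of the published FCBF pseudocode:
    order by class SU descending, walk from the head removing every later
    feature predominated by the current one."""
    su_c = {k: symmetrical_uncertainty(v, y) for k, v in features.items()}
    ordered = sorted(
        [k for k in features if su_c[k] >= su_threshold and su_c[k] > 0],
        key=lambda k: (-su_c[k], k),
    )
    i = 0
    while i < len(ordered):
        fp = ordered[i]
        ordered = ordered[: i + 1] + [
            fq for fq in ordered[i + 1:]
            if symmetrical_uncertainty(features[fp], features[fq]) < su_c[fq]
        ]
        i += 1
    return ordered


class TestFcbf:
    def test_label_copy_feature_selected_with_su_one(self):
        classes = ["early"] * 4 + ["late"] * 4
        m, labels = _dataset(
            {"COPY": [5, 5, 5, 5, 0, 0, 0, 0],
             "NOISE": [1, 0, 1, 0, 1, 0, 1, 0]},
            classes,
        )
        panel = ts.fcbf_select(m, labels)
        assert "COPY" in panel.transcript_ids
        assert panel.scores["COPY"] == pytest.approx(1.0)

    def test_duplicate_feature_pruned(self):
        classes = ["early"] * 4 + ["late"] * 4
        m, labels = _dataset(
            {"A": [5, 5, 5, 5, 0, 0, 0, 0],
             "B": [5, 5, 5, 5, 0, 0, 0, 0]},
            classes,
        )
        panel = ts.fcbf_select(m, labels)
        assert len(panel) == 1

    def test_matches_reference_implementation(self, rng):
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        classes = ["late" if v == 0 else "early" for v in y]
        rows = {
            "P1": y * 3.0 + rng.normal(0, 0.3, n),
            "P2": -y * 2.0 + rng.normal(0, 0.4, n),
            "P3": y * 1.5 + rng.normal(0, 0.6, n),
            "DUP": y * 3.0 + rng.normal(0, 0.3, n),
            "N1": rng.normal(0, 1, n),
            "N2": rng.normal(0, 1, n),
        }
        m, labels = _dataset(rows, classes)
        panel = ts.fcbf_select(m, labels)
        disc = {
            tid: np.searchsorted(mdl_discretize(vals, y), vals, side="left")
            for tid, vals in rows.items()
            if mdl_discretize(vals, y)
        }
        expected = reference_fcbf(disc, y)
        assert panel.transcript_ids == expected

    def test_threshold_out_of_range(self, small_tumor_dataset):
        ds = small_tumor_dataset
        with pytest.raises(DataError):
            ts.fcbf_select(ts.log2_transform(ds.matrix), ds.labels, su_threshold=1.5)


class TestAnovaF:
    def test_hand_computed_f(self):
        m, labels = _dataset(
            {"T": [1, 2, 3, 4, 5, 6]},
            ["early"] * 3 + ["late"] * 3,
        )
        panel = ts.anova_f_select(m, labels, k=1)
        assert panel.scores["T"] == pytest.approx(13.5)

    def test_flat_feature_never_beats_separated(self):
        m, labels = _dataset(
            {"FLAT": [2, 2, 2, 2], "SEP": [0, 0, 5, 5]},
            ["early", "early", "late", "late"],
        )
        panel = ts.anova_f_select(m, labels, k=1)
        assert panel.transcript_ids == ["SEP"]

    def test_f_equals_t_squared_binary(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 1, 9)
            m, labels = _dataset(
                {"T": np.concatenate([a, b])},
                ["early"] * 12 + ["late"] * 9,
            )
            panel = ts.anova_f_select(m, labels, k=1)
            t = sps.ttest_ind(a, b).statistic
            assert panel.scores["T"] == pytest.approx(t**2, rel=1e-9)

    def test_k_exceeding_feature_count(self, small_tumor_dataset):
        ds = small_tumor_dataset
        with pytest.raises(DataError):
            ts.anova_f_select(ts.log2_transform(ds.matrix), ds.labels,
                              k=ds.matrix.n_transcripts + 1)


@pytest.fixture(scope="module")
def zscored():
    cfg = ts.SimulationConfig(
        n_transcripts=60, n_informative=1,
        class_sizes={"normal": 0, "early": 40, "late": 40},
        effect_size_sd=5.0, dropout_rate=0.0, seed=7,
    )
    ds = ts.generate_dataset(cfg)
    logm = ts.log2_transform(ds.matrix)
    stats = ts.fit_zscore(logm)
    usable = [t for t in logm.transcript_ids if t not in set(stats.zero_sd)]
    z = ts.apply_zscore(logm.subset_transcripts(usable), stats)
    return z, ds


@pytest.fixture(scope="module")
def pool_setup():
    cfg = ts.SimulationConfig(
        n_transcripts=5, n_informative=1,
        class_sizes={"normal": 0, "early": 30, "late": 30},
        effect_size_sd=6.0, dropout_rate=0.0, seed=3,
    )
    ds = ts.generate_dataset(cfg)
    logm = ts.log2_transform(ds.matrix)
    pool = ts.FeaturePanel(logm.transcript_ids, method="manual")
    return logm, ds, pool


class TestL1Select:
    def test_separating_feature_survives_strong_penalty(self, zscored):
        z, ds = zscored
        panel = ts.l1_linear_select(z, ds.labels, penalty_strength=5.0)
        assert set(ds.truth) <= set(panel.transcript_ids)

    def test_huge_penalty_empties_panel(self, zscored):
        z, ds = zscored
        panel = ts.l1_linear_select(z, ds.labels, penalty_strength=1e6)
        assert len(panel) == 0

    def test_panel_size_monotone_in_penalty(self, zscored):
        z, ds = zscored
        sizes = [
            len(ts.l1_linear_select(z, ds.labels, penalty_strength=p))
            for p in [0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_requires_zscore_scale(self, small_tumor_dataset):
        ds = small_tumor_dataset
        with pytest.raises(DataError):
            ts.l1_linear_select(ts.log2_transform(ds.matrix), ds.labels)


class TestSubsetSearch:
    def test_predictive_feature_found(self, pool_setup):
        logm, ds, pool = pool_setup
        panel, trace = ts.subset_search_select(
            logm, ds.labels, pool, iterations=10, seed=0, folds=5
        )
        assert set(ds.truth) <= set(panel.transcript_ids)
        assert trace[-1] == max(trace)

    def test_single_iteration_returns_initial_best(self, pool_setup):
        logm, ds, pool = pool_setup
        panel, trace = ts.subset_search_select(
            logm, ds.labels, pool, iterations=1, seed=5, folds=5
        )
        assert len(trace) == 1
        assert "fitness" in panel.parameters

    def test_seed_determinism(self, pool_setup):
        logm, ds, pool = pool_setup
        a = ts.subset_search_select(logm, ds.labels, pool, iterations=4, seed=9, folds=5)
        b = ts.subset_search_select(logm, ds.labels, pool, iterations=4, seed=9, folds=5)
        assert a[0].transcript_ids == b[0].transcript_ids
        assert a[1] == b[1]

    def test_empty_pool_rejected(self, pool_setup):
        logm, ds, _ = pool_setup
        with pytest.raises(DataError):
            ts.subset_search_select(
                logm, ds.labels, ts.FeaturePanel([], method="manual"),
                iterations=1, seed=0,
            )


class TestPanelSerialization:
    def test_provenance_round_trips(self, tmp_path):
        panel = ts.FeaturePanel(
            ["T2", "T1"], method="anova_f",
            parameters={"k": 2}, scores={"T2": 3.0, "T1": 1.5},
        )
        panel.write(tmp_path / "panel.tsv")
        back = ts.FeaturePanel.read(tmp_path / "panel.tsv")
        assert back.transcript_ids == ["T2", "T1"]
        assert back.method == "anova_f"
        assert back.parameters == {"k": 2}

    def test_duplicates_rejected(self):
        with pytest.raises(DataError):
            ts.FeaturePanel(["A", "A"], method="x")
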