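"""ICC(3,1), reliability categories, and the experiment orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phaselag import (ExperimentConfig, PopulationConfig, ScorePair,
                      classify_reliability, icc_3_1, icc_from_pairs,
                      icc_table_from_scores, run_experiment, run_scheme,
                      SegmentationScheme)


def icc_oracle(x):
    """First-principles two-way sums-of-squares ICC(3,1)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ms_r = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    ss_c = n * ((x.mean(0) - grand) ** 2).sum()
    ms_e = (((x - grand) ** 2).sum() - (n - 1) * ms_r - ss_c) \
        / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


class TestICC:
    def test_additive_session_offset_gives_one(self):
        s1 = np.array([0.3, 0.5, 0.9, 1.4])
        x = np.column_stack([s1, s1 + 0.25])
        res = icc_3_1(x)
        assert res.icc == pytest.approx(1.0, abs=1e-9)
        assert res.ci_low == pytest.approx(1.0, abs=1e-6)
        assert res.p_value < 1e-12

    def test_reversed_ranks_give_negative_icc_clipped_to_zero(self):
        res = icc_3_1(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        assert res.icc < 0
        assert res.icc_clipped == 0.0
        assert res.category == "poor"

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_first_principles_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        x = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
        assert icc_3_1(x).icc == pytest.approx(icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc3_including_ci_and_p(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        x = rng.normal(size=(15, 2)) + 2.0 * rng.normal(size=(15, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "session": np.tile([1, 2], 15),
            "score": x.ravel()})
        ref = pg.intraclass_corr(df, targets="subject", raters="session",
                                 ratings="score").set_index("Type")
        row = ref.loc["ICC(C,1)"]  # two-way consistency, single measure
        res = icc_3_1(x)
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        assert res.p_value == pytest.approx(row["pval"], rel=1e-8)
        lo, hi = row["CI95"]  # pingouin rounds the CI to 2 decimals
        assert res.ci_low == pytest.approx(lo, abs=6e-3)
        assert res.ci_high == pytest.approx(hi, abs=6e-3)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
            res = icc_3_1(x)
            assert res.ci_low <= res.icc <= res.ci_high

    def test_constant_table_degenerates_to_one(self):
        res = icc_3_1(np.full((5, 2), 3.3))
        assert res.icc == 1.0 and res.ci_low == res.ci_high == 1.0
        assert np.isnan(res.p_value)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_3_1(np.array([[1.0, 2.0], [2.0, 3.0]]))

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            icc_3_1(np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 1.0]]))

    def test_from_score_pairs(self):
        pairs = [ScorePair(subject_id=i, session1_value=v,
                           session2_value=v + 0.1)
                 for i, v in enumerate((0.2, 0.5, 0.8, 0.4))]
        assert icc_from_pairs(pairs).icc == pytest.approx(1.0)


class TestClassification:
    @pytest.mark.parametrize("value,expected", [
        (0.0, "poor"), (0.39, "poor"),
        (0.40, "fair"), (0.59, "fair"), (0.595, "fair"),
        (0.60, "good"), (0.62, "good"), (0.74, "good"), (0.745, "good"),
        (0.75, "excellent"), (1.0, "excellent"),
    ])
    def test_convention_with_contiguous_boundaries(self, value, expected):
        assert classify_reliability(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_reliability(-0.1)
        with pytest.raises(ValueError):
            classify_reliability(1.1)


def tiny_population(**kw):
    base = dict(n_subjects=5, n_channels=6, sampling_rate=128.0,
                segment_lengths=(30, 30, 30, 30, 24), seed=17)
    base.update(kw)
    return PopulationConfig(**base)


class TestRunExperiment:
    def test_tidy_outputs_and_provenance(self):
        cfg = ExperimentConfig(
            population=tiny_population(),
            approaches=("constant_amount",),
            methods=("dbwpli",),
            metrics=("whole_brain", "swi"),
            n_surrogates=8)
        res = run_experiment(cfg)
        assert set(res.scores.columns) == {
            "subject", "session", "approach", "n_epochs", "epoch_length",
            "method", "metric", "value"}
        # 5 subjects x 2 sessions x 4 combos x 2 metrics
        assert len(res.scores) == 5 * 2 * 4 * 2
        assert len(res.icc_table) == 4 * 2
        assert set(res.icc_table.n_subjects) == {5}
        assert res.manifest["population"]["n_subjects"] == 5
        assert res.manifest["exclusions"] == []

    def test_constant_amount_combos_share_underlying_samples(self):
        # whole-brain PLI from 120 x 1 s and 20 x 6 s must come from the
        # same selected data: re-running yields identical scores tables
        cfg = ExperimentConfig(population=tiny_population(),
                               approaches=("constant_amount",),
                               methods=("pli",), metrics=("whole_brain",),
                               n_surrogates=2)
        a = run_experiment(cfg).scores
        b = run_experiment(cfg).scores
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_data_excludes_subject_per_scheme(self):
        # 60 s per session cannot satisfy (120 x 1 s) but satisfies small combos
        pop = tiny_population(segment_lengths=(30, 30))
        scheme = SegmentationScheme("short_epochs", ((30, 1), (120, 1)))
        res = run_scheme(pop, scheme, methods=("pli",),
                         metrics=("whole_brain",))
        got = set(res.scores.n_epochs)
        assert got == {30}
        assert len(res.manifest["exclusions"]) == 10  # 5 subjects x 2 sessions
        row120 = res.icc_table[res.icc_table.n_epochs == 120]
        assert row120.empty  # no scores at all for the starved combo

    def test_cells_with_fewer_than_three_subjects_marked_unavailable(self):
        scores = pd.DataFrame([
            dict(subject=s, session=sess, approach="short_epochs",
                 n_epochs=30, epoch_length=1, method="pli",
                 metric="whole_brain", value=0.1 * s + 0.01 * sess)
            for s in (0, 1) for sess in (1, 2)])
        table = icc_table_from_scores(scores)
        assert table.category.iloc[0] == "unavailable"
        assert np.isnan(table.icc.iloc[0])

    def test_no_between_subject_signal_gives_low_icc(self):
        # identical traits: the expected ICC is ~0; average replicate
        # cohorts to beat the large sampling spread of a single ICC
        iccs = []
        for seed in (17, 18, 19):
            pop = tiny_population(n_subjects=12, coupling_sd_between=0.0,
                                  session_noise_sd=0.05,
                                  segment_lengths=(30, 30), seed=seed)
            scheme = SegmentationScheme("short_epochs", ((30, 1),))
            res = run_scheme(pop, scheme, methods=("dbwpli",),
                             metrics=("whole_brain",))
            iccs.append(res.icc_table.icc.iloc[0])
        assert abs(np.mean(iccs)) < 0.35

    def test_strong_trait_no_state_noise_gives_high_icc(self):
        pop = tiny_population(n_subjects=8, coupling_sd_between=0.15,
                              session_noise_sd=0.0, sensor_noise_sd=1.0)
        scheme = SegmentationScheme("short_epochs", ((120, 1),))
        res = run_scheme(pop, scheme, methods=("dbwpli",),
                         metrics=("whole_brain",))
        assert res.icc_table.icc.iloc[0] > 0.9

    def test_icc_clipping_never_negative_in_table(self):
        pop = tiny_population(n_subjects=6, coupling_sd_between=0.0)
        scheme = SegmentationScheme("short_epochs", ((30, 1), (30, 2)))
        res = run_scheme(pop, scheme, methods=("pli", "dbwpli"),
                         metrics=("whole_brain",))
        assert (res.icc_table.icc_clipped.dropna() >= 0).all()
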