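import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replibio import io, preprocess
from replibio.preprocess import FULL, MEC, POV, PreprocessConfig, group_key

from conftest import biorep_design, build_matrix


def group_matrix(values, label="B1", condition="NT", log_transformed=True):
    """3-biorep single-group matrix from {sample_idx: [intensities]} lists."""
    design = biorep_design(label, condition, n=len(values))
    cols = {d.sample_id: v for d, v in zip(design, values)}
    counts = {sid: [1.0] * len(v) for sid, v in cols.items()}
    q = build_matrix(counts, intensity=cols, log_transformed=log_transformed)
    return q, design


class TestClassifyMissingness:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ((10.0, 11.0, 12.0), FULL),
            ((10.0, 11.0, np.nan), POV),
            ((10.0, np.nan, np.nan), POV),  # two missing still partially observed
            ((np.nan, np.nan, np.nan), MEC),
        ],
    )
    def test_three_replicate_patterns(self, pattern, expected):
        q, design = group_matrix([[p] for p in pattern])
        classes = preprocess.classify_missingness(q, design)
        assert classes.loc["P1", group_key("B1", "NT")] == expected

    def test_partition_is_exhaustive_and_exclusive(self, biorep_study):
        q_nt, _, design = biorep_study
        classes = preprocess.classify_missingness(
            preprocess.log2_transform(q_nt), design
        )
        assert classes.isin([FULL, POV, MEC]).all().all()
        assert not classes.isna().any().any()


class TestMedianNormalize:
    def test_two_columns_shift_to_grand_median(self):
        q, _ = group_matrix([[8.0, 10.0, 12.0], [18.0, 20.0, 22.0], [9.0, 15.0, 21.0]])
        out, shifts = preprocess.median_normalize(q)
        meds = out.intensity.median(axis=0)
        assert np.allclose(meds, 15.0, atol=1e-12)
        assert shifts.iloc[0] == 5.0 and shifts.iloc[1] == -5.0

    def test_single_column_unchanged(self):
        q, _ = group_matrix([[1.0, 2.0, 9.0]])
        out, shifts = preprocess.median_normalize(q)
        pd.testing.assert_frame_equal(out.intensity, q.intensity)
        assert shifts.iloc[0] == 0.0

    def test_all_missing_column_rejected(self):
        q, _ = group_matrix([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="all-missing"):
            preprocess.median_normalize(q)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=8), st.floats(-20, 20))
    def test_additive_shift_preserves_differences(self, column, offset):
        q, _ = group_matrix([column, [v + offset for v in column]])
        out, _ = preprocess.median_normalize(q)
        for col in q.intensity.columns:
            before = np.diff(q.intensity[col].to_numpy())
            after = np.diff(out.intensity[col].to_numpy())
            assert np.allclose(before, after, atol=1e-12)


class TestMeanCenter:
    def test_group_means_equalized(self):
        q, design = group_matrix([[3.0, 5.0], [5.0, 7.0]])  # column means 4 and 6
        out, _ = preprocess.mean_center(q, design[:2])
        assert np.allclose(out.intensity.mean(axis=0), 5.0, atol=1e-12)

    def test_idempotent(self):
        q, design = group_matrix([[3.0, 5.0, 1.0], [5.0, 7.0, 2.0], [0.0, 1.0, 4.0]])
        once, _ = preprocess.mean_center(q, design)
        twice, _ = preprocess.mean_center(once, design)
        assert np.allclose(once.intensity, twice.intensity, atol=1e-12)

    def test_centering_is_within_groups(self):
        # two groups keep their overall offset relative to each other
        q1, d1 = group_matrix([[10.0, 12.0], [12.0, 14.0]], label="B1")
        d2 = biorep_design("control_gfp_nls", "NT", n=2)
        cols = {**{d.sample_id: q1.intensity[d.sample_id].tolist() for d in d1[:2]},
                **{d.sample_id: [0.0, 2.0] for d in d2}}
        q = build_matrix({k: [1.0, 1.0] for k in cols}, intensity=cols, log_transformed=True)
        out, _ = preprocess.mean_center(q, d1[:2] + d2)
        bait_mean = out.intensity[[d.sample_id for d in d1[:2]]].mean().mean()
        ctrl_mean = out.intensity[[d.sample_id for d in d2]].mean().mean()
        assert bait_mean - ctrl_mean == pytest.approx(11.0)


class TestSlsa:
    def test_identical_columns_impute_observed_value(self):
        col = [float(i) for i in range(1, 11)]
        c3 = col.copy()
        c3[4] = np.nan  # protein P5 missing in the third replicate only
        q, design = group_matrix([col, col, c3])
        classes = preprocess.classify_missingness(q, design)
        out = preprocess.impute_slsa(q, classes, design)
        # the two observed siblings are globally identical to the third column
        assert out.intensity.iloc[4, 2] == pytest.approx(5.0, abs=1e-9)

    def test_observed_entries_bitwise_unchanged(self, biorep_study):
        q_nt, _, design = biorep_study
        q = preprocess.log2_transform(q_nt)
        classes = preprocess.classify_missingness(q, design)
        out = preprocess.impute_slsa(q, classes, design)
        observed = q.intensity.notna()
        assert (out.intensity.to_numpy()[observed.to_numpy()] == q.intensity.to_numpy()[observed.to_numpy()]).all()
        # FULL/MEC entries untouched: still missing where MEC
        for key in classes.columns:
            label, cond = key.split("|")
            cols = [d.sample_id for d in design if d.label == label and d.condition == cond]
            mec_rows = classes.index[classes[key] == MEC]
            assert out.intensity.loc[mec_rows, cols].isna().all().all()

    def test_beats_column_median_imputation(self):
        rng = np.random.default_rng(7)
        n = 120
        base = rng.normal(20, 3, size=n)
        truth = np.column_stack([base + rng.normal(0, 0.3, n) + shift for shift in (0.0, 0.5, -0.4)])
        masked = truth.copy()
        holes = rng.choice(n, size=25, replace=False)
        masked[holes, 2] = np.nan
        q, design = group_matrix(list(masked.T))
        classes = preprocess.classify_missingness(q, design)
        out = preprocess.impute_slsa(q, classes, design)
        col = q.intensity.columns[2]
        slsa_err = np.median(np.abs(out.intensity[col].to_numpy()[holes] - truth[holes, 2]))
        med_err = np.median(np.abs(np.nanmedian(masked[:, 2]) - truth[holes, 2]))
        assert slsa_err < med_err


class TestDetQuantile:
    def test_matches_declared_quantile_rule(self):
        # last 5 proteins missing in the entire group; each column observes 1..95
        col = np.arange(1.0, 101.0)
        intensity = np.column_stack([col, col, col])
        intensity[-5:, :] = np.nan
        q, design = group_matrix(list(intensity.T))
        classes = preprocess.classify_missingness(q, design)
        out = preprocess.impute_detquantile(q, classes, design)
        expected = 0.2 * np.quantile(col[:-5], 0.01, method="linear")
        assert expected == pytest.approx(0.2 * 1.94, abs=1e-12)
        assert (out.intensity.iloc[-5:, :] == expected).all().all()

    def test_factor_one_median_equals_column_median(self):
        intensity = np.column_stack([np.arange(1.0, 11.0)] * 3)
        intensity[-2:, :] = np.nan
        q, design = group_matrix(list(intensity.T))
        classes = preprocess.classify_missingness(q, design)
        cfg = PreprocessConfig(detquantile_q=0.5, detquantile_factor=1.0)
        out = preprocess.impute_detquantile(q, classes, design, cfg)
        assert out.intensity.iloc[-1, 0] == np.median(np.arange(1.0, 9.0))

    def test_imputed_below_observed_minimum(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            col = rng.uniform(5, 30, size=40)
            full = np.column_stack([col, col, col])
            full[-3:, :] = np.nan
            q, design = group_matrix(list(full.T))
            classes = preprocess.classify_missingness(q, design)
            out = preprocess.impute_detquantile(q, classes, design)
            assert (out.intensity.iloc[-1, :] < np.nanmin(col[:-3])).all()

    def test_deterministic_and_observed_untouched(self):
        intensity = np.column_stack([np.arange(1.0, 21.0)] * 3)
        intensity[-4:, :] = np.nan
        q, design = group_matrix(list(intensity.T))
        classes = preprocess.classify_missingness(q, design)
        out1 = preprocess.impute_detquantile(q, classes, design)
        out2 = preprocess.impute_detquantile(q, classes, design)
        pd.testing.assert_frame_equal(out1.intensity, out2.intensity, check_exact=True)
        observed = q.intensity.notna()
        assert (out1.intensity.to_numpy()[observed.to_numpy()] == q.intensity.to_numpy()[observed.to_numpy()]).all()


class TestPresenceFilter:
    def test_two_of_three_patterns(self):
        patterns = [
            (10.0, 11.0, 12.0),  # 3/3 -> keep
            (10.0, 11.0, np.nan),  # 2/3 -> keep
            (10.0, np.nan, np.nan),  # 1/3 -> drop
            (np.nan, np.nan, np.nan),  # 0/3 -> drop
            (np.nan, 11.0, 12.0),  # 2/3 -> keep
            (np.nan, np.nan, 12.0),  # 1/3 -> drop
        ]
        q, design = group_matrix([[p[i] for p in patterns] for i in range(3)])
        presence = preprocess.presence_filter(q, design)
        kept = set(presence.index[presence[group_key("B1", "NT")]])
        assert kept == {"P1", "P2", "P5"}

    def test_decisions_use_preimputation_masks(self, biorep_study):
        q_nt, _, design = biorep_study
        q = preprocess.log2_transform(q_nt)
        before = preprocess.presence_filter(q, design)
        classes = preprocess.classify_missingness(q, design)
        imputed = preprocess.impute_slsa(q, classes, design)
        # recompute on the original masks after imputing: survivor set unchanged
        after = preprocess.presence_filter(q, design)
        pd.testing.assert_frame_equal(before, after)
        # imputation must not be able to rescue a failing protein
        assert (preprocess.presence_filter(imputed, design).to_numpy() >= before.to_numpy()).all()


class TestPreprocessMatrix:
    def test_full_chain_reports_and_contracts(self, biorep_study):
        q_nt, _, design = biorep_study
        proc = preprocess.preprocess_matrix(q_nt, design)
        assert proc.q.log_transformed
        # control groups fully imputed (POV by SLSA, MEC by DetQuantile)
        control_cols = [d.sample_id for d in design if d.label == "control_gfp_nls" and d.condition == "NT"]
        assert not proc.q.intensity[control_cols].isna().any().any()
        assert set(proc.report) == {"class_counts", "median_shifts", "center_shifts", "presence_survivors"}
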