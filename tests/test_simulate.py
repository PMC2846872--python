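"""Synthetic cohort generation and cohort CSV round-tripping."""

import numpy as np
import pandas as pd
import pytest

from panelrfe import (
    PANEL,
    generate_cohort,
    load_reference_spec,
    read_cohort,
    write_cohort,
)


class TestGenerateCohort:
    def test_paired_structure_and_label_balance(self, cohort_170):
        assert len(cohort_170) == 340
        y = cohort_170.y
        assert (y == 1).sum() == (y == -1).sum() == 170
        # every subject appears exactly once per phase
        per_subject = cohort_170.frame.groupby("subject_id")["phase"].nunique()
        assert (per_subject == 2).all()

    def test_seed_determinism_is_bitwise(self, default_spec):
        a = generate_cohort(default_spec)
        b = generate_cohort(default_spec)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        c = generate_cohort(load_reference_spec(n_subjects=170, seed=1))
        assert not np.array_equal(a.X, c.X)

    def test_moment_recovery_at_large_n(self):
        """Each analyte's empirical mean/SD per phase lands within 5 SE of
        its spec at n = 10^4 subjects."""
        n = 10_000
        spec = load_reference_spec(n_subjects=n, seed=42)
        cohort = generate_cohort(spec)
        for phase, mean_attr, sd_attr in (("pre", "pre_mean", "pre_sd"),
                                          ("post", "post_mean", "post_sd")):
            block = cohort.phase_frame(phase)[PANEL.names].to_numpy()
            for j, idx in enumerate(PANEL.indices):
                m = getattr(spec.measures[idx], mean_attr)
                s = getattr(spec.measures[idx], sd_attr)
                se_mean = s / np.sqrt(n)
                se_sd = s / np.sqrt(2 * (n - 1))
                assert abs(block[:, j].mean() - m) < 5 * se_mean
                assert abs(block[:, j].std(ddof=1) - s) < 5 * se_sd

    @pytest.mark.parametrize("rho", [0.0, 0.8])
    def test_within_subject_correlation(self, rho):
        spec = load_reference_spec(n_subjects=4000, seed=9,
                                   within_subject_corr=rho)
        cohort = generate_cohort(spec)
        pre, post = cohort.complete_pairs()
        # correlation of a pair of null analytes and one shifted analyte
        for name in ("HDL", "MAO", "K"):
            r = np.corrcoef(pre[name], post[name])[0, 1]
            assert abs(r - rho) < 0.05

    def test_analyte_cross_correlation_hook(self):
        spec = load_reference_spec(n_subjects=3000, seed=13)
        corr = np.eye(41)
        corr[0, 1] = corr[1, 0] = 0.7
        cohort = generate_cohort(spec, analyte_corr=corr)
        pre = cohort.phase_frame("pre")
        r = np.corrcoef(pre["TP"], pre["ALB"])[0, 1]
        assert abs(r - 0.7) < 0.05

    def test_values_untruncated_and_finite(self, cohort_170):
        assert np.isfinite(cohort_170.X).all()


class TestCohortIO:
    def test_round_trip_identity(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path)
        back = read_cohort(path)
        assert back.dropped_rows == 0
        assert np.array_equal(back.y, small_cohort.y)
        np.testing.assert_allclose(back.X, small_cohort.X, rtol=0, atol=1e-12)

    def test_missing_value_rows_dropped_and_counted(self, tmp_path):
        cohort = generate_cohort(load_reference_spec(n_subjects=2, seed=0))
        frame = cohort.frame.copy()
        frame.loc[1, "MAO"] = np.nan
        path = tmp_path / "holes.csv"
        frame.to_csv(path, index=False)
        back = read_cohort(path)
        assert len(back) == 3
        assert back.dropped_rows == 1

    def test_200_subjects_with_30_incomplete_yield_170_pairs(self, tmp_path):
        """Subjects with missing measurements are removed, leaving the study
        size of 170 complete pre/post pairs."""
        cohort = generate_cohort(load_reference_spec(n_subjects=200, seed=3))
        frame = cohort.frame.copy()
        incomplete = [f"s{i + 1:03d}" for i in range(30)]
        frame.loc[frame["subject_id"].isin(incomplete), "GLU"] = np.nan
        path = tmp_path / "partial.csv"
        frame.to_csv(path, index=False)
        back = read_cohort(path)
        pre, post = back.complete_pairs()
        assert len(pre) == len(post) == 170
        assert back.dropped_rows == 60

    def test_malformed_inputs_name_the_offence(self, tmp_path, small_cohort):
        path = tmp_path / "bad.csv"

        frame = small_cohort.frame.copy()
        frame.loc[2, "phase"] = "during"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="during"):
            read_cohort(path)

        frame = small_cohort.frame.copy()
        frame["MAO"] = frame["MAO"].astype(object)
        frame.loc[5, "MAO"] = "high"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="MAO"):
            read_cohort(path)

        frame = small_cohort.frame.rename(columns={"PHOS": "PHOSPHATE"})
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="header"):
            read_cohort(path)
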