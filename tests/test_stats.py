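"""Percent-baseline correction, outlier screening and paired condition tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

import flowphys as fp


class TestBaselineCorrect:
    def test_hand_computed_values(self):
        assert fp.baseline_correct(110.0, 100.0) == pytest.approx(10.0)
        assert fp.baseline_correct(100.0, 100.0) == 0.0
        assert fp.baseline_correct(600.0, 100.0) == pytest.approx(500.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(fp.stats.BaselineError):
            fp.baseline_correct(5.0, 0.0)

    @given(
        x=st.floats(-1e6, 1e6),
        bl=st.floats(0.01, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_definition_and_linearity(self, x, bl):
        got = fp.baseline_correct(x, bl)
        assert got == pytest.approx((x - bl) / bl * 100.0, rel=1e-12, abs=1e-9)
        assert fp.baseline_correct(bl, bl) == 0.0

    def test_vectorized(self):
        out = fp.baseline_correct(np.array([110.0, 90.0]), 100.0)
        assert np.allclose(out, [10.0, -10.0])


class TestRemoveOutliers:
    def test_gross_outlier_flagged(self):
        kept, flags = fp.remove_outliers(np.array([1.0, 1.1, 0.9, 1.05, 12.0]))
        assert flags.tolist() == [False, False, False, False, True]
        assert len(kept) == 4

    def test_too_few_values_untouched_with_warning(self):
        with pytest.warns(UserWarning):
            kept, flags = fp.remove_outliers(np.array([1.0, 9.0]))
        assert len(kept) == 2 and not flags.any()

    def test_null_flag_rate_is_small(self):
        rng = np.random.default_rng(8)
        any_flagged = 0
        reps = 300
        for _ in range(reps):
            _, flags = fp.remove_outliers(rng.standard_normal(20))
            any_flagged += flags.any()
        assert any_flagged / reps < 0.10  # Bonferroni keeps family rate ~5%


class TestOneSampleT:
    def test_closed_form_example(self):
        res = fp.one_sample_t(np.array([2.0, -1.0, 3.0, 0.0, 1.0]))
        assert res.t == pytest.approx(1.4142, abs=1e-4)
        assert res.df == 4
        assert res.estimate == pytest.approx(1.0)
        assert res.p == pytest.approx(0.2302, abs=1e-4)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_p_matches_t_cdf_brute_force(self, rng):
        x = rng.standard_normal(15) + 0.4
        res = fp.one_sample_t(x)
        p = 2 * (1 - sstats.t.cdf(abs(res.t), df=14))
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_zero_variance_sentinel(self):
        res = fp.one_sample_t(np.array([1.0, 1.0, 1.0, 1.0]))
        assert res.degenerate and np.isinf(res.t) and res.p == 0.0
        res0 = fp.one_sample_t(np.zeros(4))
        assert res0.degenerate and res0.t == 0.0 and res0.p == 1.0


class TestPairedTests:
    def test_antisymmetry_is_exact(self, rng):
        a = rng.standard_normal(12) + 1.0
        b = rng.standard_normal(12)
        r_ab, _ = fp.paired_difference_test(a, b, "ab")
        r_ba, _ = fp.paired_difference_test(b, a, "ba")
        assert r_ab.t == -r_ba.t
        assert r_ab.estimate == -r_ba.estimate
        assert r_ab.p == r_ba.p and r_ab.df == r_ba.df
        assert r_ab.ci_low == -r_ba.ci_high and r_ab.ci_high == -r_ba.ci_low

    def test_insufficient_pairs_named_in_error(self):
        tv = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2", "s2"],
                "condition": ["boredom", "flow"] * 2,
                "variable": "hr_mean",
                "channel": "",
                "band": "",
                "baseline": "closed",
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="boredom vs flow"):
            fp.paired_condition_test(tv, "boredom", "flow", "hr_mean")

    def test_condition_test_uses_pairwise_complete_subjects(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(24):
            for cond in ("boredom", "flow", "frustration"):
                if cond == "flow" and i == 0:
                    continue  # one flow-incomplete subject
                if cond == "frustration" and i == 1:
                    continue  # one frustration-incomplete subject
                rows.append(
                    {
                        "subject": f"s{i}",
                        "condition": cond,
                        "variable": "hr_mean",
                        "channel": "",
                        "band": "",
                        "baseline": "closed",
                        "value": rng.standard_normal(),
                    }
                )
        tv = pd.DataFrame(rows)
        res, _ = fp.paired_condition_test(tv, "boredom", "flow", "hr_mean")
        assert res.n + res.n_outliers == 23
        res2, _ = fp.paired_condition_test(
            tv, "flow", "frustration", "hr_mean"
        )
        assert res2.n + res2.n_outliers == 22


class TestAggregateCurves:
    def _corrected(self):
        rows = []
        for subject, val in (("s1", 10.0), ("s2", 20.0)):
            for minute in (1, 2, 3):
                rows.append(
                    {
                        "subject": subject,
                        "condition": "flow",
                        "variable": "hr_mean",
                        "channel": "",
                        "band": "",
                        "baseline": "closed",
                        "minute": minute,
                        "value": val,
                    }
                )
        return pd.DataFrame(rows)

    def test_cross_subject_minute_mean(self):
        curves, outliers = fp.aggregate_curves(self._corrected())
        m3 = curves[(curves.minute == 3)]
        assert m3["mean"].iloc[0] == 15.0 and m3["n"].iloc[0] == 2
        assert len(outliers) == 0

    def test_whole_phase_summary_row_present(self):
        curves, _ = fp.aggregate_curves(self._corrected())
        summary = curves[curves.minute == 0]
        assert summary["mean"].iloc[0] == 15.0

    def test_excluded_subject_absent_from_means(self):
        df = self._corrected()
        df = df[df.subject != "s2"]  # exclusion upstream: rows never present
        curves, _ = fp.aggregate_curves(df)
        assert (curves["n"] == 1).all()
        assert (curves["mean"] == 10.0).all()


class TestEmitResultsTable:
    def _result(self, label, p):
        return fp.TestResult(label, 2.0, 9, 0.1, 1.9, 1.0, p, 10)

    def test_significance_threshold(self):
        full, sig = fp.emit_results_table(
            [self._result("a", 0.04), self._result("b", 0.06)], alpha=0.05
        )
        assert len(full) == 2
        assert sig["comparison"].tolist() == ["a"]

    def test_empty_input_keeps_headers(self):
        full, sig = fp.emit_results_table([])
        assert list(full.columns)[:7] == [
            "comparison", "t", "df", "ci_low", "ci_high", "estimate", "p",
        ]
        assert len(full) == 0 and len(sig) == 0
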