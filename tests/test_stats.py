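"""Statistical toolkit: hand-computed values, oracles, null calibration."""

import math

import numpy as np
import pytest

from tiltcal import (
    icc_2_1,
    one_way_anova,
    pearson_r,
    t_test_two_sample,
    validation_report,
    validation_table,
)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # cov = 4/3, sd_x = sd_y = sqrt(5/3)  ->  r = 4/5
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_is_explicit_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])  # too short


class TestICC:
    def test_identical_raters_give_one(self):
        m = np.tile(np.array([[1.0], [4.0], [9.0], [2.0]]), (1, 3))
        assert icc_2_1(m) == pytest.approx(1.0)

    def test_matches_brute_force_anova_oracle(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        n, k = m.shape
        # independent mean-squares computation, cell by cell
        grand = m.mean()
        msr = k * sum((row.mean() - grand) ** 2 for row in m) / (n - 1)
        msc = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
        sse = sum(
            (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
            for i in range(n)
            for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_2_1(m) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(7)
        subj = rng.normal(0, 2, size=12)
        m = subj[:, None] + rng.normal(0, 1, size=(12, 3))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        # single-rater absolute agreement under the two-way random model
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(m) == pytest.approx(icc2, abs=1e-9)

    def test_null_white_noise_near_zero(self):
        rng = np.random.default_rng(123)
        m = rng.normal(size=(200, 3))
        assert abs(icc_2_1(m)) < 0.1

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc_2_1(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestTTest:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        t, p = t_test_two_sample(a, a)
        assert t == 0.0 and p == 1.0

    def test_swap_negates_statistic(self):
        a = [1.0, 2.0, 3.5, 2.2]
        b = [2.0, 3.0, 4.0, 2.9]
        t1, p1 = t_test_two_sample(a, b)
        t2, p2 = t_test_two_sample(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_degenerate_constant_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            t_test_two_sample([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_calibrated(self):
        """Under the null (same normal law), rejection rate at alpha=0.05
        is 0.05 +/- 0.01 over 10,000 simulations."""
        rng = np.random.default_rng(2024)
        a = rng.normal(size=(10_000, 12))
        b = rng.normal(size=(10_000, 12))
        from scipy import stats as sps

        p = sps.ttest_ind(a, b, axis=1).pvalue
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        a = [1.0, 2.5, 3.0, 4.2]
        b = [2.0, 3.1, 5.0, 6.5, 4.4]
        f, p_f = one_way_anova([a, b])
        t, p_t = t_test_two_sample(a, b)
        assert f == pytest.approx(t**2, rel=1e-9)
        assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_degenerate_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            one_way_anova([[3.0, 3.0], [3.0, 3.0]])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        groups = rng.normal(size=(3, 10_000, 8))
        from scipy import stats as sps

        p = sps.f_oneway(groups[0], groups[1], groups[2], axis=1).pvalue
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)


class TestValidationReport:
    def test_perfect_agreement(self):
        actual = np.array([-20.0, -5.0, 3.0, 14.0, 28.0])
        rep = validation_report(actual, actual)
        assert rep.mean_diff == 0.0 and rep.sd_diff == 0.0
        assert rep.pct_within_5deg == 100.0
        assert rep.direction_accuracy_pct == 100.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.t_p_value == pytest.approx(1.0)

    def test_constant_offset(self):
        actual = np.array([-10.0, 0.0, 10.0, 20.0])
        rep = validation_report(actual, actual + 10.0)
        assert rep.mean_diff == pytest.approx(10.0)
        assert rep.pct_within_5deg == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_hand_computed_symmetric_shrink(self):
        rep = validation_report([-10.0, 10.0], [-6.0, 6.0])
        assert rep.mean_diff == pytest.approx(0.0)
        assert rep.abs_mean_diff == pytest.approx(4.0)
        assert rep.pct_within_5deg == 100.0

    def test_fields_match_straight_line_recompute(self):
        rng = np.random.default_rng(5)
        actual = rng.uniform(-30, 30, 40)
        measured = actual + rng.normal(0, 4, 40)
        rep = validation_report(actual, measured)
        diff = measured - actual
        assert rep.mean_actual == pytest.approx(actual.mean(), rel=1e-12)
        assert rep.sd_measured == pytest.approx(measured.std(ddof=1), rel=1e-12)
        assert rep.mean_diff == pytest.approx(diff.mean(), rel=1e-12)
        assert rep.sd_abs_diff == pytest.approx(np.abs(diff).std(ddof=1), rel=1e-12)
        assert rep.pct_within_5deg == pytest.approx(100 * np.mean(np.abs(diff) < 5))
        sel = np.abs(actual) >= 2.0
        assert rep.direction_accuracy_pct == pytest.approx(
            100 * np.mean(np.sign(measured[sel]) == np.sign(actual[sel]))
        )

    def test_direction_accuracy_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(11)
        actual = rng.uniform(-30, 30, 60)
        measured = actual + rng.normal(0, 3, 60)
        base = validation_report(actual, measured).direction_accuracy_pct
        warped = np.sign(measured) * np.abs(measured) ** 1.7  # monotone, sign-preserving
        assert validation_report(actual, warped).direction_accuracy_pct == base

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            validation_report([1.0, 2.0], [1.0])


class TestValidationTable:
    @staticmethod
    def _rows():
        import pandas as pd

        rng = np.random.default_rng(8)
        tilt = np.concatenate([rng.uniform(-30, 30, 20), [-10.0, 5.0, 15.0, 25.0]])
        sex = np.array(["male"] * 12 + ["female"] * 12)
        return pd.DataFrame(
            {
                "true_tilt_deg": tilt,
                "estimated_tilt_deg": tilt + rng.normal(0, 2, tilt.size),
                "sex": sex,
            }
        )

    def test_subgroup_ns_sum_to_total(self):
        rows = self._rows()
        table = validation_table(rows).set_index("label")
        assert table.loc["male", "n"] + table.loc["female", "n"] == table.loc["all", "n"]
        non5 = table.loc["non_multiples_of_5", "n"]
        assert (
            table.loc["male_non_multiples_of_5", "n"]
            + table.loc["female_non_multiples_of_5", "n"]
            == non5
        )
        # the four appended tilts are exact multiples of 5
        assert non5 == table.loc["all", "n"] - 4

    def test_report_serialization_round_trip(self, tmp_path):
        import json

        import pandas as pd

        from tiltcal.stats import write_report

        table = validation_table(self._rows())
        write_report(table, tmp_path / "report.tsv")
        write_report(table, tmp_path / "report.json")
        tsv = pd.read_csv(tmp_path / "report.tsv", sep="\t")
        assert list(tsv["label"]) == list(table["label"])
        data = json.loads((tmp_path / "report.json").read_text())
        assert data[0]["n"] == int(table.iloc[0]["n"])
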