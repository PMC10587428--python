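import numpy as np
import pandas as pd
import pytest

from tackit.cohort import (
    PairedSample,
    build_summary_table,
    correlate,
    fold_summary,
    paired_compare,
    rm_anova_tukey,
    significance_marker,
)


def _sample(a, b):
    a = np.asarray(a, dtype=float)
    return PairedSample(tuple(f"S{i}" for i in range(a.size)), a, np.asarray(b, dtype=float))


class TestPairedCompare:
    def test_identical_conditions(self):
        s = _sample([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = paired_compare(s)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_shift_degenerate(self):
        s = _sample([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        res = paired_compare(s)
        assert res.degenerate
        assert res.mean_diff == pytest.approx(-1.0)

    def test_matches_scipy_on_real_data(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.063, 0.02, 10)
        b = a + rng.normal(0.018, 0.01, 10)
        from scipy import stats

        res = paired_compare(_sample(a, b))
        want = stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(float(want.statistic))
        assert res.p_value == pytest.approx(float(want.pvalue))

    def test_power_against_table_effect(self):
        # heart k2 difference (0.063 vs 0.081, SDs ~0.02, n = 10) should be
        # detected more often than the 5% false-positive rate
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 300
        for _ in range(reps):
            subject = rng.normal(0.0, 0.015, 10)  # shared between-subject term
            a = 0.063 + subject + rng.normal(0.0, 0.012, 10)
            b = 0.081 + subject + rng.normal(0.0, 0.012, 10)
            if paired_compare(_sample(a, b)).p_value <= 0.05:
                rejections += 1
        assert rejections / reps > 0.5

    def test_wilcoxon_branch(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 0.2, 12)
        shift = rng.normal(0.5, 0.1, 12)
        res = paired_compare(_sample(a, a + shift), method="wilcoxon")
        assert res.method == "wilcoxon"
        assert res.p_value < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PairedSample(("a", "b"), np.array([1.0]), np.array([1.0, 2.0]))


class TestCorrelate:
    def test_perfect_linear(self):
        a = np.arange(1.0, 9.0)
        res = correlate(_sample(a, 2.0 * a))
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_negative_association_sign(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 30)
        res = correlate(_sample(a, -a + rng.normal(0, 0.2, 30)))
        assert res.r < 0

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(500):
            a, b = rng.normal(0, 1, (2, 10))
            rs.append(correlate(_sample(a, b)).r)
        se = 1.0 / np.sqrt(9) / np.sqrt(500)
        assert abs(np.mean(rs)) < 3 * se

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, (2, 15))
        res = correlate(_sample(a, b))
        want = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert abs(res.r - want) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate(_sample([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def _long(values: np.ndarray, conds) -> pd.DataFrame:
    n, k = values.shape
    return pd.DataFrame(
        {
            "subject": np.repeat([f"S{i}" for i in range(n)], k),
            "condition": list(conds) * n,
            "value": values.ravel(),
        }
    )


class TestRmAnovaTukey:
    def test_identical_conditions_null(self):
        rng = np.random.default_rng(6)
        base = rng.normal(10, 2, 8)
        x = np.tile(base[:, None], (1, 3)) + rng.normal(0, 0.5, (8, 3))
        res = rm_anova_tukey(_long(x, "ABC"))
        assert res.p_value > 0.01
        x_same = np.tile(base[:, None], (1, 3))
        res_same = rm_anova_tukey(_long(x_same, "ABC"))
        assert res_same.f == 0.0
        assert all(p.p_value == 1.0 for p in res_same.tukey)

    def test_shifted_condition_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (10, 3))
        x[:, 2] += 10.0
        res = rm_anova_tukey(_long(x, "ABC"))
        assert res.p_value < 1e-6
        pair_ps = {(p.cond_a, p.cond_b): p.p_value for p in res.tukey}
        assert pair_ps[("A", "C")] < 1e-4 and pair_ps[("B", "C")] < 1e-4
        assert pair_ps[("A", "B")] > 0.05

    def test_f_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (9, 4)) + rng.normal(0, 1, (9, 1))
        df = _long(x, "ABCD")
        res = rm_anova_tukey(df)
        sm = AnovaRM(df, "value", "subject", within=["condition"]).fit()
        assert res.f == pytest.approx(float(sm.anova_table["F Value"].iloc[0]), rel=1e-8)
        assert res.p_value == pytest.approx(float(sm.anova_table["Pr > F"].iloc[0]), rel=1e-6)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, (10, 3))
        x[:, 1] += 0.8
        res = rm_anova_tukey(_long(x, "ABC"))

        def f_stat(mat):
            grand = mat.mean()
            ss_c = mat.shape[0] * np.sum((mat.mean(0) - grand) ** 2)
            ss_s = mat.shape[1] * np.sum((mat.mean(1) - grand) ** 2)
            ss_e = np.sum((mat - grand) ** 2) - ss_c - ss_s
            return (ss_c / 2) / (ss_e / 18)

        obs = f_stat(x)
        perm = np.empty(2000)
        for i in range(2000):
            shuffled = np.array([row[rng.permutation(3)] for row in x])
            perm[i] = f_stat(shuffled)
        p_perm = np.mean(perm >= obs)
        mc_se = np.sqrt(p_perm * (1 - p_perm) / 2000) + 1e-4
        assert abs(res.p_value - p_perm) < 4 * mc_se + 0.01

    def test_incomplete_design_rejected(self):
        df = _long(np.ones((4, 3)), "ABC").iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_tukey(df)


class TestFoldSummary:
    def test_identical_subjects_conventions_agree(self):
        fs = fold_summary(np.full(5, 1.5), np.full(5, 1.0))
        assert fs.mean_of_ratios == pytest.approx(1.5)
        assert fs.ratio_of_means == pytest.approx(1.5)
        assert fs.sd_of_ratios == 0.0

    def test_reference_ratios(self):
        # cortex/heart uptake from cohort means: 0.83/0.61 and 1.77/0.69
        assert fold_summary(np.array([0.83]), np.array([0.61])).ratio_of_means == pytest.approx(1.4, abs=0.05)
        assert fold_summary(np.array([1.77]), np.array([0.69])).ratio_of_means == pytest.approx(2.6, abs=0.05)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_summary(np.array([1.0]), np.array([0.0]))


class TestSummaryTable:
    @staticmethod
    def _metrics(n=6):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(n):
            for tracer, mean in (("acac", 0.61), ("ac", 0.69)):
                rows.append(
                    {
                        "subject_id": f"S{i:02d}",
                        "organ": "heart_lv",
                        "metric": "K1_1tc",
                        "tracer": tracer,
                        "value": rng.normal(mean, 0.05),
                    }
                )
        return pd.DataFrame(rows)

    def test_aggregation_matches_direct_oracle(self):
        m = self._metrics()
        table = build_summary_table(m)
        for _, row in table.iterrows():
            vals = m.query("tracer == @row.tracer")["value"]
            assert row["mean"] == pytest.approx(vals.mean(), rel=1e-12)
            assert row["sd"] == pytest.approx(vals.std(ddof=1), rel=1e-12)

    def test_markers_backed_by_paired_test(self):
        m = self._metrics(10)
        table = build_summary_table(m)
        acac = table.query("tracer == 'acac'").iloc[0]
        ref = table.query("tracer == 'ac'").iloc[0]
        assert np.isfinite(acac["p_vs_ref"])
        assert ref["marker"] == ""  # the reference arm is never marked
        assert acac["marker"] == significance_marker(acac["p_vs_ref"])

    def test_single_subject_no_tests(self):
        m = self._metrics(1)
        table = build_summary_table(m)
        assert table["p_vs_ref"].isna().all()
        assert table["sd"].isna().all()

    def test_missing_reference_arm_rejected(self):
        m = self._metrics().query("tracer == 'acac'")
        with pytest.raises(ValueError, match="reference"):
            build_summary_table(m)

    def test_csv_round_trip(self, tmp_path):
        table = build_summary_table(self._metrics())
        path = tmp_path / "summary.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back.fillna(""), table.fillna(""), check_exact=False, rtol=1e-12
        )


class TestSignificanceMarkers:
    @pytest.mark.parametrize(
        "p,marker",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, ""), (np.nan, "")],
    )
    def test_tiers(self, p, marker):
        assert significance_marker(p) == marker
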