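"""Percent change, mixed-effects change tests, ICC, and Pearson layers."""

import numpy as np
import pandas as pd
import pytest

from enterometry.phantom import MEASUREMENTS, make_longitudinal_cohort
from enterometry.stats import (
    fit_change_over_time,
    icc_agreement,
    pearson_ci,
    percent_change,
    run_study_analysis,
)


class TestPercentChange:
    def test_decrease_is_positive(self):
        assert percent_change(19.8, 11.6) == 41

    def test_no_change_zero(self):
        assert percent_change(7.3, 7.3) == 0

    def test_increase_is_negative(self):
        assert percent_change(10.0, 12.0) == -20

    def test_unrounded_value(self):
        assert percent_change(19.8, 11.6, rounded=False) == pytest.approx(41.414, abs=1e-3)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_change(0.0, 1.0)


class TestChangeOverTime:
    def test_single_subject_rejected(self):
        tab = make_longitudinal_cohort(n_subjects=2, rng_seed=0)
        tab = tab[tab["subject_id"] == "S001"]
        with pytest.raises(ValueError, match="2 subjects"):
            fit_change_over_time(tab, "manual_volume_mL")

    def test_absent_measurement_rejected(self):
        tab = make_longitudinal_cohort(n_subjects=4, rng_seed=0)
        with pytest.raises(ValueError, match="absent"):
            fit_change_over_time(tab, "no_such_column")

    def test_recovers_timepoint_means(self):
        tab = make_longitudinal_cohort(
            n_subjects=40, timepoint_effects=(1.0, 0.6, 0.3),
            between_subject_sd=0.3, within_subject_sd=0.05, rng_seed=2,
        )
        res = fit_change_over_time(tab, "manual_volume_mL")
        observed = tab.groupby("timepoint", observed=True)["manual_volume_mL"].mean()
        for tp, mu in res.timepoint_means.items():
            assert mu == pytest.approx(observed[tp], rel=0.02)
        assert res.p_value < 1e-6

    def test_strong_decline_detected_consistently(self):
        """Power check: the reference-scale decline is detected essentially
        always in cohorts of the study's size."""
        detected = sum(
            fit_change_over_time(
                make_longitudinal_cohort(n_subjects=20, rng_seed=500 + i),
                "manual_volume_mL",
            ).p_value < 0.05
            for i in range(20)
        )
        assert detected >= 19

    def test_runs_with_missing_followups(self):
        tab = make_longitudinal_cohort(
            n_subjects=20, n_missing_month6=2, n_missing_all_followup=1, rng_seed=3)
        res = fit_change_over_time(tab, "length_cm")
        assert res.n_observations == len(tab)
        assert res.n_subjects == 20


def brute_force_icc2(x, y):
    """Independent oracle: mean squares from a statsmodels OLS two-way ANOVA."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    n = len(x)
    df = pd.DataFrame({
        "rating": np.concatenate([x, y]),
        "subject": list(range(n)) * 2,
        "rater": ["A"] * n + ["B"] * n,
    })
    fit = smf.ols("rating ~ C(subject) + C(rater)", df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    msr = tab.loc["C(subject)", "sum_sq"] / tab.loc["C(subject)", "df"]
    msc = tab.loc["C(rater)", "sum_sq"] / tab.loc["C(rater)", "df"]
    mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    k = 2
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_vectors_perfect_agreement(self):
        v = np.array([3.0, 8.0, 1.0, 6.0, 9.0, 2.0])
        res = icc_agreement(v, v)
        assert res.icc_estimate == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_six_pair_toy_table_matches_anova_oracle(self):
        x = np.array([10.0, 12.0, 8.0, 14.0, 11.0, 9.0])
        y = np.array([11.0, 13.5, 8.5, 13.0, 12.5, 9.5])
        res = icc_agreement(x, y)
        assert res.icc_estimate == pytest.approx(brute_force_icc2(x, y), abs=1e-9)

    def test_fuzzed_tables_match_anova_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            x = rng.normal(rng.uniform(-5, 20), rng.uniform(0.5, 5), n)
            y = rng.uniform(0.2, 1.5) * x + rng.normal(0, rng.uniform(0.1, 4), n)
            res = icc_agreement(x, y)
            assert res.icc_estimate == pytest.approx(brute_force_icc2(x, y), abs=1e-9)

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 20))
            x = rng.normal(10, 3, n)
            y = 0.9 * x + rng.normal(0, 1.5, n)
            res = icc_agreement(x, y)
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile(["A", "B"], n),
                "ratings": np.column_stack([x, y]).ravel(),
            })
            tab = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="ratings")
            row = tab[tab["Type"] == "ICC(A,1)"].iloc[0]
            assert res.icc_estimate == pytest.approx(row["ICC"], abs=1e-9)
            # pingouin reports its CI rounded to 2 decimals
            assert res.ci_low == pytest.approx(row["CI95"][0], abs=0.006)
            assert res.ci_high == pytest.approx(row["CI95"][1], abs=0.006)

    def test_noise_only_agreement_poor(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 3, 40)
        y = x.mean() + rng.normal(0, 30, 40)
        assert icc_agreement(x, y).band == "poor"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            icc_agreement([5.0] * 6, [5.0] * 6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            icc_agreement([1, 2, 3, 4], [1, 2, 3, 4])

    def test_missing_pairs_dropped(self):
        x = np.array([1, 2, 3, 4, 5, 6, np.nan])
        y = np.array([1.1, 2.2, 2.9, 4.1, 5.2, 5.9, 3.0])
        assert icc_agreement(x, y).n_pairs == 6


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_ci(x, -x).r == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        from scipy import stats as sps
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            x = rng.normal(0, rng.uniform(0.5, 3), n)
            y = rng.uniform(-1, 1) * x + rng.normal(0, rng.uniform(0.5, 3), n)
            res = pearson_ci(x, y)
            r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert res.r == pytest.approx(r, abs=1e-9)
            z, se = np.arctanh(r), 1 / np.sqrt(n - 3)
            zc = sps.norm.ppf(0.975)
            assert res.ci_low == pytest.approx(np.tanh(z - zc * se), abs=1e-9)
            assert res.ci_high == pytest.approx(np.tanh(z + zc * se), abs=1e-9)
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = 2 * sps.t.sf(abs(t), n - 2)
            assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, 3, 4, np.nan, 6])
        y = np.array([2.0, 4, 6, 8, 10, np.nan])
        assert pearson_ci(x, y).n_pairs == 4

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


@pytest.fixture(scope="module")
def results():
    tab = make_longitudinal_cohort(
        n_subjects=20, n_missing_month6=2, n_missing_all_followup=1, rng_seed=17)
    return run_study_analysis(tab)


class TestStudyAnalysis:

    def test_all_measurements_tested(self, results):
        assert set(results.change_tests["measurement"]) == set(MEASUREMENTS)

    def test_reference_scale_cohort_all_significant(self, results):
        assert (results.change_tests["p_value"] < 0.05).all()

    def test_percent_changes_for_both_intervals(self, results):
        assert len(results.percent_changes) == len(MEASUREMENTS) * 2

    def test_correlation_matrix_symmetric_unit_diagonal(self, results):
        mat = results.correlations.to_numpy()
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert np.all(np.abs(mat) <= 1.0)

    def test_agreement_result_sane(self, results):
        a = results.agreement
        assert a.ci_low <= a.icc_estimate <= a.ci_high
        assert a.band in ("poor", "moderate", "good", "excellent")

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_study_analysis(pd.DataFrame())
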