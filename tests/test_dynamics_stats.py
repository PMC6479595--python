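import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyto3d import (
    AttachmentSeries,
    accuracy_regression,
    compare_groups,
    fit_log_logistic,
    format_percent,
    gdd_from_temperature,
    generate_attachments,
    log_logistic,
    percent_difference,
)


class TestThermalTime:
    def test_constant_two_days(self):
        idx = pd.date_range("2024-05-01", periods=48, freq="h")
        out = gdd_from_temperature(pd.Series(25.0, index=idx), t_base=5.0)
        assert out["gdd"].iloc[-1] == pytest.approx(40.0)
        assert not out["incomplete"].any()

    def test_below_base_accumulates_nothing(self):
        idx = pd.date_range("2024-01-01", periods=72, freq="h")
        out = gdd_from_temperature(pd.Series(2.0, index=idx), t_base=5.0)
        assert (out["gdd"] == 0).all()

    def test_mixed_series_matches_hand_computed_daily_means(self):
        rng = np.random.default_rng(0)
        idx = pd.date_range("2024-06-01", periods=96, freq="h")
        temps = pd.Series(rng.uniform(0, 35, 96), index=idx)
        out = gdd_from_temperature(temps, t_base=5.0)
        expected = 0.0
        for day in range(4):
            day_mean = temps.iloc[day * 24:(day + 1) * 24].mean()
            expected += max(0.0, day_mean - 5.0)
        assert out["gdd"].iloc[-1] == pytest.approx(expected)

    def test_cumulative_is_monotone_and_additive(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2024-06-01", periods=240, freq="h")
        temps = pd.Series(rng.uniform(-5, 35, 240), index=idx)
        out = gdd_from_temperature(temps)
        assert (out["gdd"].diff().dropna() >= 0).all()
        first = gdd_from_temperature(temps.iloc[:120])["gdd"].iloc[-1]
        second = gdd_from_temperature(temps.iloc[120:])["gdd"].iloc[-1]
        assert out["gdd"].iloc[-1] == pytest.approx(first + second)

    def test_gappy_days_flagged(self):
        idx = pd.date_range("2024-06-01", periods=30, freq="h")
        out = gdd_from_temperature(pd.Series(20.0, index=idx))
        assert out["incomplete"].iloc[-1]  # second day has only 6 records

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            gdd_from_temperature(pd.Series(dtype=float))


class TestLogLogisticFit:
    def test_noiseless_recovery_of_generating_triple(self):
        gdd = np.arange(500.0, 1201.0, 50.0)
        series = generate_attachments((6.62, 1000.18, -6.37), gdd)
        fit = fit_log_logistic(series)
        assert fit.converged
        assert fit.a == pytest.approx(6.62, rel=1e-3)
        assert fit.x0 == pytest.approx(1000.18, rel=1e-3)
        assert fit.b == pytest.approx(-6.37, rel=1e-3)
        assert fit.r_squared > 0.999

    def test_constant_response_flagged_degenerate(self):
        series = AttachmentSeries(
            gdd=np.array([100.0, 200.0, 300.0, 400.0]),
            attachments=np.full(4, 3.0),
        )
        fit = fit_log_logistic(series)
        assert fit.degenerate and not fit.converged
        assert fit.a == pytest.approx(3.0)

    def test_random_triples_recovered_to_relative_tolerance(self):
        rng = np.random.default_rng(7)
        gdd = np.arange(300.0, 1501.0, 60.0)
        for _ in range(10):
            a = rng.uniform(2, 10)
            x0 = rng.uniform(450, 1350)
            b = -rng.uniform(2, 9)
            fit = fit_log_logistic(generate_attachments((a, x0, b), gdd))
            assert abs(fit.a - a) / a < 1e-3
            assert abs(fit.x0 - x0) / x0 < 1e-3
            assert abs(fit.b - b) / abs(b) < 1e-3

    def test_fitted_curve_monotone_over_data_range(self):
        gdd = np.arange(500.0, 1201.0, 50.0)
        series = generate_attachments(
            (6.62, 1000.18, -6.37), gdd, noise_sd=0.3, seed=1
        )
        fit = fit_log_logistic(series)
        pred = fit.predict(np.linspace(500, 1200, 200))
        assert (np.diff(pred) >= -1e-9).all()

    def test_too_few_points_rejected(self):
        series = AttachmentSeries(gdd=np.array([1.0, 2.0, 3.0]),
                                  attachments=np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError, match="4 points"):
            fit_log_logistic(series)


class TestSeriesValidation:
    def test_non_increasing_gdd_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            AttachmentSeries(gdd=np.array([1.0, 1.0]), attachments=np.zeros(2))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            AttachmentSeries(gdd=np.array([1.0, 2.0]),
                             attachments=np.array([-0.1, 0.2]))


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        cmp_ = compare_groups({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert cmp_.p_anova == 1.0 and cmp_.p_tukey == 1.0
        assert not cmp_.significant

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        cmp_ = compare_groups(
            {
                "low": np.zeros(5) + rng.normal(0, 1e-6, 5),
                "high": np.full(5, 10.0) + rng.normal(0, 1e-6, 5),
            }
        )
        assert cmp_.significant
        assert cmp_.p_tukey < 1e-6

    def test_f_statistic_matches_textbook_computation(self):
        groups = {"g1": np.array([3.0, 5.0, 4.0]), "g2": np.array([8.0, 9.0, 10.0])}
        cmp_ = compare_groups(groups)
        values = np.concatenate(list(groups.values()))
        grand = values.mean()
        ss_between = sum(
            len(g) * (g.mean() - grand) ** 2 for g in groups.values()
        )
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        f_expected = (ss_between / 1) / (ss_within / 4)
        assert cmp_.f_statistic == pytest.approx(f_expected)

    def test_p_value_agrees_with_permutation_test(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.2, 1.0, 8)
        cmp_ = compare_groups({"a": a, "b": b})
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:8].mean() - pooled[8:].mean()) >= observed:
                count += 1
        p_perm = count / n_perm
        assert cmp_.p_anova == pytest.approx(p_perm, abs=0.03)

    def test_single_group_and_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"only": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [2.0, 3.0]})


class TestAccuracyRegression:
    def test_perfect_agreement(self):
        x = np.array([10.0, 15.0, 20.0, 25.0])
        rep = accuracy_regression(x, x)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-10)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_absorbed_by_intercept(self):
        x = np.array([10.0, 15.0, 20.0, 25.0])
        rep = accuracy_regression(x + 2.0, x)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(2.0)
        assert rep.rmse == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(5)
        actual = rng.uniform(10, 30, 40)
        estimated = 1.02 * actual - 0.4 + rng.normal(0, 0.7, 40)
        rep = accuracy_regression(estimated, actual)
        x = np.column_stack([np.ones(40), actual])
        beta = np.linalg.lstsq(x, estimated, rcond=None)[0]
        resid = estimated - x @ beta
        assert rep.intercept == pytest.approx(beta[0])
        assert rep.slope == pytest.approx(beta[1])
        assert rep.rmse == pytest.approx(np.sqrt(np.mean(resid**2)))
        assert rep.percent_error == pytest.approx(
            rep.rmse / actual.mean() * 100.0
        )

    def test_zero_variance_actual_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            accuracy_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestPercentDifference:
    def test_equal_inputs_are_zero(self):
        assert percent_difference(5.0, 5.0, "control") == 0.0

    def test_reference_convention_matters(self):
        assert percent_difference(112.0, 82.0, "infected") == pytest.approx(
            30.0 / 82.0 * 100.0
        )
        assert percent_difference(0.2, 0.12, "control") == pytest.approx(40.0)

    def test_symmetric_in_absolute_difference(self):
        assert percent_difference(10.0, 4.0, "control") == pytest.approx(
            percent_difference(4.0, 10.0, "infected")
        )

    def test_homogeneous_under_common_scaling(self):
        v = percent_difference(23.0, 13.0, "infected")
        assert percent_difference(2.3, 1.3, "infected") == pytest.approx(v)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0, "infected")
        with pytest.raises(ValueError):
            percent_difference(1.0, 2.0, "elsewhere")

    def test_display_truncates_toward_zero(self):
        assert format_percent(106.7) == 106
        assert format_percent(76.9) == 76
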