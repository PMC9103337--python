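import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovitherm import synth
from ovitherm.aging import (
    AgingRecord,
    category_summary,
    fit_regression,
    normalize_series,
    records_to_frame,
    repeatability_stats,
)
from ovitherm.errors import NormalizationError, RegressionError
from ovitherm.sizing import AirChamberMeasurement, Flag
from ovitherm.thermo_io import Category


class TestRepeatability:
    def test_textbook_sample_sd(self):
        r = repeatability_stats([100, 102, 98, 101, 99])
        assert r.mean_A_b == pytest.approx(100.0)
        assert r.sd_A_b == pytest.approx(np.sqrt(2.5), rel=1e-12)
        assert r.sd_percent == pytest.approx(1.5811, abs=1e-4)
        assert r.n == 5

    def test_identical_values_zero_sd(self):
        assert repeatability_stats([50, 50, 50]).sd_percent == 0.0

    def test_single_value_is_na(self):
        r = repeatability_stats([100])
        assert not r.available
        assert r.n == 1

    def test_failed_fits_dropped(self):
        r = repeatability_stats([100.0, np.nan, 102.0, np.nan])
        assert r.n == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1.0, 1e4), min_size=2, max_size=12),
        st.floats(0.01, 100.0),
    )
    def test_sd_percent_scale_invariant(self, values, gain):
        base = repeatability_stats(values)
        scaled = repeatability_stats([gain * v for v in values])
        if base.available:
            assert scaled.sd_percent == pytest.approx(base.sd_percent, rel=1e-9)


class TestNormalize:
    def test_division_by_first_day(self):
        assert normalize_series([200, 220, 260]) == pytest.approx([1.0, 1.1, 1.3])

    def test_zero_first_value_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_series([0, 10])

    def test_length_one(self):
        assert normalize_series([42.0]) == pytest.approx([1.0])


def record(egg, day, a, b=None, weight=60.0, cat=Category.M, failed=False):
    b = b if b is not None else a * 1.2
    flags = {Flag.FIT_FAILED} if failed else set()
    m = AirChamberMeasurement(a_mm=min(a, b), b_mm=max(a, b), flags=flags)
    return AgingRecord(
        egg_id=egg, category=cat, days_since_laying=day, weight_g=weight, measurement=m
    )


class TestCategorySummary:
    def test_two_egg_mean_and_sd(self):
        recs = [record("e1", 3, 5.0, 5.0), record("e2", 3, 7.0, 7.0)]
        s = category_summary(recs)
        assert len(s) == 1
        assert s.loc[0, "a_mean"] == pytest.approx(6.0)
        assert s.loc[0, "a_sd"] == pytest.approx(np.sqrt(2.0), abs=1e-4)

    def test_identical_eggs_zero_sd(self):
        recs = [record("e1", 3, 6.0), record("e2", 3, 6.0)]
        s = category_summary(recs)
        assert s.loc[0, "a_sd"] == 0.0

    def test_failed_fit_excluded(self):
        recs = [
            record("e1", 3, 5.0),
            record("e2", 3, 7.0),
            record("e3", 3, 100.0, failed=True),
        ]
        s = category_summary(recs)
        assert s.loc[0, "n"] == 2
        assert s.loc[0, "a_mean"] == pytest.approx(6.0)

    def test_weight_loss_relative_to_first_day(self):
        recs = [
            record("e1", 3, 5.0, weight=60.0),
            record("e1", 5, 5.5, weight=59.2),
            record("e2", 3, 5.0, weight=58.0),
            record("e2", 5, 5.5, weight=57.4),
        ]
        s = category_summary(recs)
        day5 = s[s["day"] == 5].iloc[0]
        assert day5["weight_loss_mean"] == pytest.approx((0.8 + 0.6) / 2)
        assert s[s["day"] == 3].iloc[0]["A_norm"] == 1.0

    def test_valid_column_roundtrip(self):
        recs = [record("e1", 3, 5.0), record("e1", 5, 6.0, failed=True)]
        df = records_to_frame(recs)
        assert df["valid"].tolist() == [True, False]


def ols_oracle(x, y, order):
    """Closed-form OLS with coefficient standard errors, the cross-check."""
    X = np.vander(x, order + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(x) - (order + 1)
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


class TestRegression:
    def test_exact_quadratic(self):
        x = np.arange(6.0)
        y = 1 + 2 * x + 3 * x**2
        fit = fit_regression(x, y, order=2)
        assert fit.coefficients == pytest.approx((1.0, 2.0, 3.0), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_linear_has_two_coefficients(self):
        x = np.arange(5.0)
        fit = fit_regression(x, 2.5 - 0.5 * x, order=1)
        assert len(fit.coefficients) == 2
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_quadratic_within_three_oracle_se(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 5, 15)
        truth = (1.0, 0.2, -0.01)
        y = truth[0] + truth[1] * x + truth[2] * x**2 + rng.normal(0, 0.01, x.size)
        fit = fit_regression(x, y, order=2)
        beta, se = ols_oracle(x, y, 2)
        assert fit.coefficients == pytest.approx(tuple(beta), rel=1e-9)
        for est, tr, s in zip(fit.coefficients, truth, se):
            assert abs(est - tr) < 3 * s

    def test_r_squared_of_own_fit_is_one(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 4, 12)
        y = rng.normal(size=12)
        fit = fit_regression(x, y, order=2)
        refit = fit_regression(x, fit.predict(x), order=2)
        assert refit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(RegressionError):
            fit_regression([0, 1, 2], [1, 2, 3], order=2)

    def test_constant_y_flagged_undefined(self):
        fit = fit_regression(np.arange(5.0), np.ones(5), order=1)
        assert not fit.r2_defined


class TestCohortPipeline:
    def test_zero_noise_cohort_recovers_exact_law(self):
        records, truth = synth.generate_cohort(
            n_per_category=4,
            seed=5,
            weight_noise_sd=0.0,
            area_noise_frac=0.0,
            c_noise_sd_mm=0.0,
            rate_jitter=0.0,
        )
        summary = category_summary(records)
        for cat, grp in summary.groupby("category"):
            fit = fit_regression(grp["weight_loss_mean"], grp["A_norm"], order=2)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
            b1, b2 = truth[truth["category"] == cat].iloc[0][["beta1", "beta2"]]
            assert fit.coefficients == pytest.approx((1.0, b1, b2), abs=1e-9)

    def test_default_noise_cohort_keeps_high_r2(self):
        records, _ = synth.generate_cohort(n_per_category=10, seed=2)
        summary = category_summary(records)
        for _, grp in summary.groupby("category"):
            fit = fit_regression(grp["weight_loss_mean"], grp["A_norm"], order=2)
            assert fit.r_squared >= 0.95
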