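"""Gestational models: day regression, sandwich covariance, DE, ANOVA, ratios."""

import numpy as np
import pandas as pd
import pytest

from mficyto.events import ConfigurationError
from mficyto.trends import (
    anova_dispatch,
    build_trend_design,
    compare_ratios,
    compare_windows,
    differential_expression,
    fit_day_regression,
    ratio_test,
    robust_trend_fit,
    sandwich_covariance,
)


class TestDayRegression:
    def test_noiseless_linear_r2_one(self):
        days = np.repeat([10.5, 12.5, 14.5, 16.5], 3)
        X = pd.DataFrame({"MP": 0.5 - 0.02 * days, "neutrophil": 0.1 + 0.02 * days})
        res = fit_day_regression(X, days)
        assert res.training_r2 == pytest.approx(1.0, abs=1e-9)

    def test_permuted_labels_negative_cv(self):
        rng = np.random.default_rng(0)
        cvs = []
        for seed in range(20):
            days = np.repeat(np.arange(10.5, 18.6), 3)
            X = pd.DataFrame(rng.normal(0.3, 0.05, size=(len(days), 2)),
                             columns=["MP", "neutrophil"])
            res = fit_day_regression(X, days, seed=seed)
            cvs.append(res.cv_r2_mean)
        assert np.mean(cvs) <= 0

    def test_more_features_than_samples_refused(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(4, 6)))
        days = np.array([10.5, 11.5, 12.5, 13.5])
        with pytest.raises(ConfigurationError):
            fit_day_regression(X, days)
        # ridge path accepts it
        res = fit_day_regression(X, days, ridge_alpha=1.0)
        assert np.isfinite(res.training_r2)

    def test_window_filter(self):
        days = np.repeat(np.arange(10.5, 18.6), 2)
        X = pd.DataFrame({"f": np.linspace(0, 1, len(days))})
        early = fit_day_regression(X, days, window="early")
        late = fit_day_regression(X, days, window="late")
        assert early.n_samples == 8 and late.n_samples == 10


class TestCompareWindows:
    def test_identical_fold_scores(self):
        r = fit_day_regression(
            pd.DataFrame({"f": np.linspace(0, 1, 12)}),
            np.repeat([10.5, 11.5, 12.5, 13.5], 3),
        )
        cmp_res = compare_windows(r, r)
        assert cmp_res.ratio == 1.0
        assert cmp_res.p_value == 1.0

    def test_ratio_of_means(self):
        a = fit_day_regression(
            pd.DataFrame({"f": np.linspace(0, 1, 12)}),
            np.repeat([10.5, 11.5, 12.5, 13.5], 3),
        )
        b_scores = a.cv_r2 * 0.5
        import dataclasses

        b = dataclasses.replace(a, cv_r2=b_scores)
        assert compare_windows(a, b).ratio == pytest.approx(2.0)

    def test_t_matches_textbook_formula(self):
        import dataclasses

        base = fit_day_regression(
            pd.DataFrame({"f": np.linspace(0, 1, 12)}),
            np.repeat([10.5, 11.5, 12.5, 13.5], 3),
        )
        a = dataclasses.replace(base, cv_r2=np.array([0.8, 0.7, 0.9, 0.6]))
        b = dataclasses.replace(base, cv_r2=np.array([0.4, 0.3, 0.5]))
        res = compare_windows(a, b)
        x, y = a.cv_r2, b.cv_r2
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-9)


class TestRobustTrend:
    def _fixed_design(self):
        rng = np.random.default_rng(7)
        day = np.tile(np.arange(10.5, 18.6, 1.0), 3)[:20]
        comp = np.array((["PB"] * 7) + (["EV"] * 7) + (["TIS"] * 6))
        y = 0.2 + 0.01 * day + 0.05 * (comp == "EV") + rng.normal(0, 0.03, 20)
        return y, day, comp

    def test_sandwich_matches_brute_force_oracle(self):
        y, day, comp = self._fixed_design()
        fit = robust_trend_fit(y, day, comp)
        X = build_trend_design(day, comp).to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        oracle = sandwich_covariance(X, resid)
        assert np.allclose(fit.cov.to_numpy(), oracle, atol=1e-10)

    def test_equal_magnitude_residuals_reduce_to_classical(self):
        # |e_i| = c for all i makes HC0 equal sigma^2 (X'X)^-1 with sigma^2 = c^2
        X = build_trend_design(np.array([10.5, 11.5, 12.5, 13.5, 14.5, 15.5]))
        Xv = X.to_numpy()
        e = np.array([0.2, -0.2, 0.2, -0.2, 0.2, -0.2])
        hc0 = sandwich_covariance(Xv, e)
        classical = 0.04 * np.linalg.inv(Xv.T @ Xv)
        assert np.allclose(hc0, classical, atol=1e-10)

    def test_robust_converges_to_classical_homoskedastic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 10_000
        day = rng.uniform(10.5, 18.5, n)
        y = 1.0 + 0.1 * day + rng.normal(0, 1, n)
        fit = robust_trend_fit(y, day)
        X = build_trend_design(day)
        ols = sm.OLS(y, X).fit()
        ratio = fit.table.set_index("term")["robust_se"] / ols.bse
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_reference_level_is_pb(self):
        y, day, comp = self._fixed_design()
        fit = robust_trend_fit(y, day, comp)
        terms = set(fit.table["term"])
        assert "compartment[EV]" in terms and "compartment[TIS]" in terms
        assert "compartment[PB]" not in terms

    def test_quadratic_recovery_single_seed(self):
        rng = np.random.default_rng(9)
        day = np.repeat(np.arange(10.5, 18.6, 1.0), 3)
        t = day - day.mean()
        y = 0.1 + 0.02 * t - 0.008 * t**2 + rng.normal(0, 0.01, len(day))
        fit = robust_trend_fit(y, day, quadratic=True)
        row = fit.table.set_index("term").loc["day2"]
        assert row["estimate"] < 0 and row["p"] < 0.05

    def test_rank_deficient_rejected(self):
        day = np.full(10, 12.5)
        with pytest.raises(ConfigurationError):
            robust_trend_fit(np.random.default_rng(0).normal(size=10), day)


class TestDifferentialExpression:
    def _medians(self, rng, n_mice=5, n_markers=8, shift=None):
        base = rng.normal(2.0, 0.3, size=(n_mice, n_markers))
        df = pd.DataFrame(base, columns=[f"mk{i}" for i in range(n_markers)])
        if shift:
            df[shift[0]] += shift[1]
        return df

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(10)
        a = self._medians(rng)
        out = differential_expression(a, a.copy())
        assert not out["significant"].any()

    def test_bonferroni_multiplication(self):
        # raw p = 0.01 over 40 markers adjusts to 0.4
        from statsmodels.stats.multitest import multipletests

        p = np.full(40, 0.01)
        _, adj, _, _ = multipletests(p, method="bonferroni")
        assert np.allclose(adj, 0.4)

    def test_injected_shift_detected(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(10):
            a = self._medians(rng, shift=("mk0", 1.5))
            b = self._medians(rng)
            out = differential_expression(a, b).set_index("marker")
            hits += bool(out.loc["mk0", "significant"])
        assert hits >= 9

    def test_small_group_skipped(self):
        a = pd.DataFrame({"mk0": [1.0], "mk1": [2.0]})
        b = pd.DataFrame({"mk0": [1.0, 1.1], "mk1": [2.0, 2.1]})
        out = differential_expression(a, b)
        assert out.empty


class TestAnovaDispatch:
    def test_identical_groups_boundary(self):
        g = {k: np.array([1.0, 2.0, 3.0]) for k in "ABC"}
        res = anova_dispatch(g)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_f_three(self):
        g = {"A": np.array([1.0, 2.0, 3.0]), "B": np.array([2.0, 3.0, 4.0]),
             "C": np.array([3.0, 4.0, 5.0])}
        res = anova_dispatch(g)
        assert res.method == "classic"
        assert res.f_statistic == pytest.approx(3.0, abs=1e-9)
        assert len(res.posthoc) == 3  # all pairwise comparisons

    def test_unequal_variances_use_welch(self):
        rng = np.random.default_rng(12)
        g = {"A": rng.normal(0, 0.1, 20), "B": rng.normal(0, 5.0, 20),
             "C": rng.normal(0, 5.0, 20)}
        res = anova_dispatch(g)
        assert res.method == "welch"

    def test_zero_variance_group_welch_branch(self):
        rng = np.random.default_rng(13)
        g = {"A": np.ones(5), "B": rng.normal(0, 1, 5), "C": rng.normal(0, 1, 5)}
        res = anova_dispatch(g)
        assert res.method == "welch"

    def test_too_few_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            anova_dispatch({"A": np.ones(3), "B": np.ones(3)})


class TestRatioTest:
    def test_identical_samples_ratio_one(self):
        x = np.array([4.0, 5.0, 6.0])
        res = ratio_test(x, x.copy())
        assert res.ratio == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.normal(50, 5, 10)
        y = rng.normal(25, 2, 10)
        a = ratio_test(x, y)
        b = ratio_test(10 * x, 10 * y)
        assert a.ratio == pytest.approx(b.ratio, rel=1e-12)
        assert a.variance == pytest.approx(b.variance, rel=1e-9)

    def test_taylor_matches_monte_carlo(self):
        rng = np.random.default_rng(15)
        x = rng.normal(10, 1, 10_000)
        y = rng.normal(5, 0.5, 10_000)
        res = ratio_test(x, y)
        mc = np.array(
            [rng.normal(10, 1, 10_000).mean() / rng.normal(5, 0.5, 10_000).mean()
             for _ in range(1000)]
        )
        assert res.variance == pytest.approx(mc.var(ddof=1), rel=0.05)

    def test_zero_control_pseudo_count(self):
        res = ratio_test(np.array([2.0, 3.0]), np.array([0.0, 2.0]))
        assert res.pseudo_count_applied
        assert np.isfinite(res.variance)

    def test_compare_ratios_finite(self):
        rng = np.random.default_rng(16)
        r1 = ratio_test(rng.normal(12, 1, 8), rng.normal(6, 0.5, 8))
        r2 = ratio_test(rng.normal(6, 1, 8), rng.normal(6, 0.5, 8))
        t, p = compare_ratios(r1, r2)
        assert np.isfinite(t) and 0 <= p <= 1
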