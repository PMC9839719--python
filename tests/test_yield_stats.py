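"""Detrending, correlations, county and panel regressions, VIF, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatyield import yield_stats as ys


class TestDetrend:
    def test_perfect_line_gives_zero_anomalies(self):
        d = ys.detrend([2000, 2001, 2002], [10.0, 20.0, 30.0])
        assert d.anomalies == pytest.approx([0.0, 0.0, 0.0], abs=1e-9)
        assert d.slope == pytest.approx(10.0)

    def test_constant_series(self):
        d = ys.detrend(np.arange(2000, 2010), np.full(10, 7.0))
        assert d.slope == pytest.approx(0.0, abs=1e-12)
        assert d.anomalies == pytest.approx(np.zeros(10), abs=1e-9)

    def test_matches_closed_form_ols(self):
        years = np.array([2000, 2001, 2002, 2003, 2004], dtype=float)
        values = np.array([3.0, 7.0, 4.0, 9.0, 6.0])
        xc = years - years.mean()
        slope = (xc * (values - values.mean())).sum() / (xc**2).sum()
        intercept = values.mean() - slope * years.mean()
        d = ys.detrend(years, values)
        assert d.anomalies == pytest.approx(values - (slope * years + intercept))

    def test_anomalies_have_no_residual_trend(self):
        rng = np.random.default_rng(2)
        years = np.arange(1979, 2020)
        d = ys.detrend(years, rng.normal(100, 10, years.size) + 1.5 * years)
        resid_slope = np.polyfit(years, d.anomalies, 1)[0]
        assert resid_slope == pytest.approx(0.0, abs=1e-9)
        assert d.anomalies.mean() == pytest.approx(0.0, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ys.InsufficientDataError):
            ys.detrend([2000, 2001], [1.0, 2.0])


class TestPearson:
    def test_proportional_series(self):
        x = ys.detrend(np.arange(6), [1.0, 5, 2, 8, 3, 9])
        r, _ = ys.pearson_correlation(x.anomalies, 2 * x.anomalies)
        assert r == pytest.approx(1.0)
        r, _ = ys.pearson_correlation(x.anomalies, -x.anomalies)
        assert r == pytest.approx(-1.0)

    def test_matches_explicit_sum_formula(self):
        xa = np.array([1.0, -2.0, 0.5, 2.0, -1.0, -0.5])
        ya = np.array([0.8, -1.0, 0.2, 1.5, -1.2, 0.1])
        xa, ya = xa - xa.mean(), ya - ya.mean()
        expected = (xa * ya).sum() / np.sqrt((xa**2).sum() * (ya**2).sum())
        r, p = ys.pearson_correlation(xa, ya)
        assert r == pytest.approx(expected, rel=1e-12)
        # p from the t transform, df = n - 2
        from scipy import stats
        t = expected * np.sqrt(4 / (1 - expected**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), rel=1e-9)

    def test_zero_variance_undefined(self):
        with pytest.raises(ys.InsufficientDataError):
            ys.pearson_correlation(np.zeros(6), np.arange(6.0))


class TestYieldRegression:
    def test_noise_free_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        years = np.arange(1980, 2020)
        dhd = rng.poisson(4.0, years.size).astype(float)
        hhd = rng.poisson(7.5, years.size).astype(float)
        y = 120.0 - 2.0 * dhd + 0.0 * hhd
        res = ys.fit_yield_regression(
            ys.detrend(years, y), ys.detrend(years, dhd), ys.detrend(years, hhd)
        )
        assert res.beta1 == pytest.approx(-2.0, abs=1e-9)
        assert res.beta2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        y = np.array([2.0, -1.0, 3.0, 0.5, -4.5])
        d1 = np.array([1.0, 0.0, 2.0, 1.0, -4.0])
        d2 = np.array([0.0, 1.0, 1.0, -1.0, -1.0])
        x = np.column_stack([np.ones(5), d1, d2])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        res = ys.fit_yield_regression(y, d1, d2)
        assert (res.beta0, res.beta1, res.beta2) == pytest.approx(tuple(beta), rel=1e-10)

    def test_perfect_collinearity_raises_with_vif_pointer(self):
        d1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ys.SingularDesignError, match="variance_inflation"):
            ys.fit_yield_regression(np.ones(5), d1, 2 * d1)

    def test_significance_uses_student_t_with_n_minus_3_df(self):
        rng = np.random.default_rng(1)
        y, d1, d2 = rng.normal(size=(3, 10))
        res = ys.fit_yield_regression(y, d1, d2)
        from scipy import stats
        expected_p = 2 * stats.t.sf(abs(res.t_stats[1]), 10 - 3)
        assert res.p_values[1] == pytest.approx(expected_p, rel=1e-9)


class TestFixedEffects:
    @staticmethod
    def _toy_panel():
        counties = ["C0", "C1", "C2"]
        years = [2000, 2001, 2002, 2003]
        rng = np.random.default_rng(4)
        rows, exp_rows = [], []
        c_eff = {"C0": 0.0, "C1": 8.0, "C2": -5.0}
        t_eff = {2000: 0.0, 2001: 2.0, 2002: 4.0, 2003: 6.0}
        for c in counties:
            for t in years:
                dhd = float(rng.poisson(4))
                hhd = float(rng.poisson(7))
                rows.append(
                    {"county_id": c, "year": t, "crop": "corn", "irrigated": 0,
                     "yield_bu_acre": 100 + c_eff[c] + t_eff[t] - 2.0 * dhd + 0.0 * hhd
                     + rng.normal(0, 1.0), "lat": 40.0}
                )
                exp_rows.append({"county_id": c, "year": t, "dhd": dhd, "hhd": hhd})
        return pd.DataFrame(rows), pd.DataFrame(exp_rows)

    def test_matches_dummy_variable_ols_oracle(self):
        panel, exp = self._toy_panel()
        fe = ys.fit_fixed_effects(panel, exp)
        # independent oracle: explicit indicator matrix + lstsq
        df = panel.merge(exp, on=["county_id", "year"])
        counties = sorted(df["county_id"].unique())
        years = sorted(df["year"].unique())
        cols = [np.ones(len(df)), df["dhd"].to_numpy(), df["hhd"].to_numpy()]
        for c in counties[1:]:
            cols.append((df["county_id"] == c).to_numpy(float))
        for t in years[1:]:
            cols.append((df["year"] == t).to_numpy(float))
        x = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(x, df["yield_bu_acre"].to_numpy(), rcond=None)
        assert fe.beta1 == pytest.approx(beta[1], abs=1e-8)
        assert fe.beta2 == pytest.approx(beta[2], abs=1e-8)
        assert fe.county_effects["C1"] == pytest.approx(beta[3], abs=1e-8)
        assert fe.year_effects[2001] == pytest.approx(beta[3 + len(counties) - 1], abs=1e-8)

    def test_noise_free_exact_recovery(self):
        counties = [f"C{i}" for i in range(4)]
        years = list(range(2000, 2006))
        rng = np.random.default_rng(9)
        rows, exp_rows = [], []
        for i, c in enumerate(counties):
            for t in years:
                dhd, hhd = float(rng.poisson(4)), float(rng.poisson(7))
                rows.append({"county_id": c, "year": t,
                             "yield_bu_acre": 100 + 3.0 * i + 1.5 * (t - 2000) - 2.0 * dhd})
                exp_rows.append({"county_id": c, "year": t, "dhd": dhd, "hhd": hhd})
        fe = ys.fit_fixed_effects(pd.DataFrame(rows), pd.DataFrame(exp_rows))
        assert fe.beta1 == pytest.approx(-2.0, abs=1e-8)
        assert fe.beta2 == pytest.approx(0.0, abs=1e-8)
        # county-effect contrasts against the reference county
        assert fe.county_effects["C2"] - fe.county_effects["C0"] == pytest.approx(6.0, abs=1e-8)

    def test_non_irrigated_filter_default(self):
        panel, exp = self._toy_panel()
        panel.loc[panel["county_id"] == "C2", "irrigated"] = 1
        fe = ys.fit_fixed_effects(panel, exp)
        assert fe.n_counties == 2


class TestVIF:
    @pytest.mark.parametrize(
        "r_target, expected_vif",
        [(0.0, 1.0), (np.sqrt(0.5), 2.0), (np.sqrt(0.75), 4.0)],
    )
    def test_closed_forms(self, r_target, expected_vif):
        # two zero-mean orthogonal equal-norm vectors give exact sample r
        x = np.array([1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0])
        y = r_target * x + np.sqrt(1 - r_target**2) * z
        res = ys.variance_inflation(x, y)
        assert abs(res.r) == pytest.approx(r_target, abs=1e-12)
        assert res.vif == pytest.approx(expected_vif, rel=1e-9)

    @given(
        a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0),
        c=st.floats(0.1, 10.0), d=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance_and_lower_bound(self, a, b, c, d):
        rng = np.random.default_rng(17)
        x = rng.poisson(4.0, 30).astype(float)
        y = rng.poisson(7.0, 30).astype(float)
        base = ys.variance_inflation(x, y)
        scaled = ys.variance_inflation(a * x + b, c * y + d)
        assert scaled.vif == pytest.approx(base.vif, rel=1e-9)
        assert base.vif >= 1.0

    def test_perfect_collinearity_is_an_error(self):
        x = np.arange(10.0)
        with pytest.raises(ys.SingularDesignError):
            ys.variance_inflation(x, 3 * x + 1)


class TestSummaries:
    @staticmethod
    def _results(lats, beta1, beta2=None, irrigated=None):
        n = len(lats)
        return pd.DataFrame(
            {
                "lat": lats,
                "beta1": beta1,
                "beta2": beta2 if beta2 is not None else np.zeros(n),
                "irrigated": irrigated if irrigated is not None else np.zeros(n, int),
            }
        )

    def test_identical_coefficients_collapse_box(self):
        df = self._results([40.1, 40.2, 39.9], [-2.0, -2.0, -2.0], beta2=[-2.0] * 3)
        out = ys.summarize_by_latitude(df)
        assert (out["median"] == -2.0).all()
        assert (out["q3"] - out["q1"] == 0).all()

    def test_quartiles_match_sorting_oracle(self):
        vals = np.array([5.0, -3.0, 1.0, 7.0, -1.0, 2.0, 0.0, 4.0, -2.0])
        df = self._results(np.full(9, 41.0), vals)
        out = ys.summarize_by_latitude(df)
        row = out[(out["band"] == 41.0) & (out["coefficient"] == "beta1")].iloc[0]
        q1, med, q3 = np.percentile(np.sort(vals), [25, 50, 75])
        assert (row["q1"], row["median"], row["q3"]) == pytest.approx((q1, med, q3))

    def test_band_assignment_rounds_to_nearest_degree(self):
        df = self._results([41.4, 41.6], [-1.0, -2.0])
        out = ys.summarize_by_latitude(df)
        assert set(out["band"]) == {41.0, 42.0}

    def test_group_separation_of_planted_effects(self):
        rng = np.random.default_rng(23)
        irr = np.array([1] * 20 + [0] * 20)
        beta1 = np.where(irr, rng.normal(0.0, 0.2, 40), rng.normal(-2.0, 0.2, 40))
        df = self._results(np.full(40, 40.0), beta1, irrigated=irr)
        out = ys.summarize_by_group(df).set_index("group")
        assert out.loc["Non-Irr/dry", "mean"] < out.loc["Irr/dry", "mean"] - 1.0
        # both mean and median are reported
        assert {"mean", "median"} <= set(out.columns)

    def test_single_group_only(self):
        df = self._results([40.0, 40.5], [-2.0, -1.5], irrigated=[1, 1])
        out = ys.summarize_by_group(df)
        assert set(out["group"]) == {"Irr/dry", "Irr/humid"}


class TestPercentImpact:
    @pytest.mark.parametrize(
        "beta, mean_yield, days, per_day, cumulative",
        [
            (-2.0, 120.0, 7.5, -1.7, -13.0),
            (-0.5, 35.0, None, -1.4, None),
            (0.0, 100.0, 5.0, 0.0, 0.0),
        ],
    )
    def test_worked_examples(self, beta, mean_yield, days, per_day, cumulative):
        got_per_day, got_cum = ys.percent_yield_impact(beta, mean_yield, days)
        assert got_per_day == per_day
        assert got_cum == cumulative

    def test_nonpositive_mean_yield_rejected(self):
        with pytest.raises(ValueError):
            ys.percent_yield_impact(-2.0, 0.0, 5.0)
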