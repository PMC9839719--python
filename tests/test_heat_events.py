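"""Percentile thresholds, day classification, exposure counting, trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatyield import heat_events as he

from conftest import make_series


def _full_year_series(years, missing_dates=(), station_id="S000"):
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    dates = dates[~dates.isin(pd.to_datetime(list(missing_dates)))]
    tmax = 20.0 + np.zeros(len(dates))
    return make_series(dates, tmax, station_id=station_id)


class TestQualityControl:
    def test_complete_series_passes_with_all_months_good(self):
        s = _full_year_series((2000, 2002))
        rep = he.station_quality_control(s, (2000, 2002))
        assert rep.passed
        assert rep.good_month_fraction == 1.0
        assert rep.month_coverage["good"].all()

    def test_one_missing_year_out_of_41_still_passes(self):
        # 12 bad months of 492 is ~2.4% bad -> well above the 90% good rule
        missing = pd.date_range("1990-01-01", "1990-12-31", freq="D")
        s = _full_year_series((1979, 2019), missing_dates=missing)
        rep = he.station_quality_control(s, (1979, 2019))
        assert rep.passed
        n_bad = (~rep.month_coverage["good"]).sum()
        assert n_bad == 12
        assert rep.good_month_fraction == pytest.approx(480 / 492)

    def test_uniform_15_percent_missingness_fails_every_month(self):
        dates = pd.date_range("2000-01-01", "2004-12-31", freq="D")
        keep = np.ones(len(dates), dtype=bool)
        keep[::7] = False  # ~14.3% of days removed in every month
        tmax = np.where(keep, 25.0, np.nan)
        s = make_series(dates, tmax)
        rep = he.station_quality_control(s, (2000, 2004))
        assert not rep.passed
        assert not rep.month_coverage["good"].any()


class TestThresholds:
    def test_degenerate_distribution_threshold_equals_value(self):
        dates = pd.date_range("1996-01-01", "2010-12-31", freq="D")
        dates = dates[dates.month.isin([5, 6, 7, 8, 9])]
        s = make_series(dates, np.full(len(dates), 30.0), twmax=np.full(len(dates), 24.0))
        thr = he.compute_thresholds(s, 0.95, (1996, 2010))
        assert thr.thr_tmax_c == pytest.approx(30.0)
        assert thr.thr_twmax_c == pytest.approx(24.0)

    def test_interpolated_percentile_matches_sorting_oracle(self):
        rng = np.random.default_rng(5)
        dates = pd.date_range("1996-05-01", periods=2400, freq="D")
        dates = dates[dates.month.isin([5, 6, 7, 8, 9])][:1000]
        values = rng.permutation(np.arange(1.0, 1001.0))[: len(dates)]
        s = make_series(dates, values, twmax=values - 5.0)
        thr = he.compute_thresholds(
            s, 0.90, (dates[0].year, dates[-1].year), min_fraction=0.0
        )
        # brute-force linear interpolation between order statistics
        v = np.sort(values)
        h = 0.90 * (len(v) - 1)
        lo = int(np.floor(h))
        expected = v[lo] + (h - lo) * (v[lo + 1] - v[lo])
        assert thr.thr_tmax_c == pytest.approx(expected)

    def test_exceedance_fraction_matches_level(self):
        rng = np.random.default_rng(7)
        dates = pd.date_range("1981-01-01", "2010-12-31", freq="D")
        dates = dates[dates.month.isin([5, 6, 7, 8, 9])]
        tmax = rng.normal(30.0, 3.0, len(dates))
        s = make_series(dates, tmax)
        thr = he.compute_thresholds(s, 0.90, (1981, 2010))
        frac = (tmax > thr.thr_tmax_c).mean()
        assert frac == pytest.approx(0.10, abs=2.0 / len(dates) + 1e-3)

    def test_insufficient_data_raises(self):
        dates = pd.date_range("2000-05-01", periods=30, freq="D")
        s = make_series(dates, np.full(30, 30.0))
        with pytest.raises(he.ThresholdError, match="S000"):
            he.compute_thresholds(s, 0.95, (1981, 2010))


def _thr(tmax=30.0, twmax=24.0):
    return he.ThresholdSet(
        station_id="S000", level=0.95, thr_tmax_c=tmax, thr_twmax_c=twmax,
        base_period=(1981, 2010), season=(5, 6, 7, 8, 9), n_days_used=4000,
    )


class TestClassification:
    @pytest.mark.parametrize(
        "tmax, twmax, expected",
        [
            (32.0, 23.0, he.DRY_HEAT),
            (32.0, 25.0, he.HUMID_HEAT),   # overlap day counts as humid, not dry
            (29.0, 25.0, he.HUMID_HEAT),
            (29.0, 23.0, he.NONE_LABEL),
            (30.0, 24.0, he.NONE_LABEL),   # exceedance is strict
            (np.nan, 23.0, he.MISSING),
        ],
    )
    def test_label_definitions(self, tmax, twmax, expected):
        assert he.classify_day(tmax, twmax, _thr()) == expected

    @given(
        tmax=st.floats(10.0, 45.0), twmax=st.floats(5.0, 35.0),
        shift=st.floats(-10.0, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shift_invariance(self, tmax, twmax, shift):
        """Adding a constant to both values and thresholds leaves labels fixed."""
        twmax = min(twmax, tmax)
        base = he.classify_day(tmax, twmax, _thr())
        shifted = he.classify_day(tmax + shift, twmax + shift,
                                  _thr(30.0 + shift, 24.0 + shift))
        assert base == shifted

    @given(tmax=st.floats(10.0, 45.0), twmax=st.floats(5.0, 35.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_raising_level_never_adds_events(self, tmax, twmax):
        twmax = min(twmax, tmax)
        lo, hi = _thr(28.0, 22.0), _thr(31.0, 25.0)
        rank = {he.NONE_LABEL: 0, he.DRY_HEAT: 1, he.HUMID_HEAT: 1}
        assert rank[he.classify_day(tmax, twmax, hi)] <= rank[he.classify_day(tmax, twmax, lo)]


class TestSeasonalCounts:
    def _labels(self, labels, start="2000-05-01"):
        dates = pd.date_range(start, periods=len(labels), freq="D")
        codes = {"D": he.DRY_HEAT, "H": he.HUMID_HEAT, "N": he.NONE_LABEL, "M": he.MISSING}
        lab = [codes[c] for c in labels]
        ex_t = [c == "D" for c in labels]  # toy: overlap-free
        ex_tw = [c == "H" for c in labels]
        return pd.DataFrame({"date": dates, "label": lab,
                             "exceeds_tmax": ex_t, "exceeds_twmax": ex_tw})

    def test_toy_window_counts(self):
        exp = he.seasonal_counts(self._labels("DDHNNHDNNN"), "S000", 2000)
        assert (exp.dhd, exp.hhd, exp.xtmax, exp.overlap) == (3, 2, 3, 0)

    def test_all_missing_counts_zero_with_flag(self):
        exp = he.seasonal_counts(self._labels("MMMMM"), "S000", 2000)
        assert exp.dhd == exp.hhd == exp.xtmax == 0
        assert exp.n_missing == exp.n_days == 5

    def test_vectorized_exposures_match_per_year_counts(self, small_config):
        from heatyield import synthetic

        s = synthetic.generate_station_weather(small_config, 0)
        thr = he.compute_thresholds(s, 0.95, small_config.base_period, small_config.season)
        fast = he.season_exposures(s, thr, small_config.season)
        labels = he.classify_days(s, thr)
        for exp in fast:
            ref = he.seasonal_counts(labels, s.station_id, exp.year, small_config.season)
            assert (exp.dhd, exp.hhd, exp.xtmax, exp.overlap) == (
                ref.dhd, ref.hhd, ref.xtmax, ref.overlap)

    def test_conservation_invariant_enforced(self):
        with pytest.raises(ValueError, match="dhd"):
            he.SeasonalExposure("S000", 2000, (5,), dhd=3, hhd=1, xtmax=5,
                                overlap=1, n_days=31, n_missing=0)


class TestOverlapFraction:
    def _exp(self, overlap, xtmax):
        return he.SeasonalExposure("S000", 2000, (5,), dhd=xtmax - overlap,
                                   hhd=overlap, xtmax=xtmax, overlap=overlap,
                                   n_days=31, n_missing=0)

    def test_complete_overlap_gives_one(self):
        assert he.overlap_fraction([self._exp(5, 5), self._exp(3, 3)]) == 1.0

    def test_no_overlap_gives_zero(self):
        assert he.overlap_fraction([self._exp(0, 7)]) == 0.0

    def test_pooled_arithmetic(self):
        assert he.overlap_fraction([self._exp(3, 10), self._exp(2, 10)]) == pytest.approx(0.25)

    def test_zero_extreme_days_is_missing_not_zero(self):
        assert np.isnan(he.overlap_fraction([self._exp(0, 0)]))


class TestFrequencyTrend:
    def test_noise_free_line(self):
        years = np.arange(1979, 2020)
        counts = 5.0 + 0.1 * (years - 1979)
        res = he.frequency_trend(counts, years)
        assert res.slope_per_year == pytest.approx(0.1)
        assert res.total_change == pytest.approx(4.0)
        assert res.p_value < 1e-20

    def test_white_noise_type_i_error(self):
        """Slope t-test rejects ~5% of pure-noise replicates."""
        rng = np.random.default_rng(11)
        years = np.arange(1979, 2020)
        rejections = sum(
            he.frequency_trend(rng.poisson(7.5, years.size), years).p_value < 0.05
            for _ in range(500)
        )
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(rejections / 500 - 0.05) < 2.5 * se

    def test_permutation_leaves_null_slope_distribution_unchanged(self):
        rng = np.random.default_rng(3)
        years = np.arange(2000, 2020)
        counts = rng.poisson(6.0, years.size).astype(float)
        slopes = [
            abs(he.frequency_trend(rng.permutation(counts), years).slope_per_year)
            for _ in range(200)
        ]
        observed = abs(he.frequency_trend(counts, years).slope_per_year)
        # under exchangeability the observed slope is not extreme
        assert (np.sum(np.array(slopes) >= observed) + 1) / 201 > 0.01

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError, match="10"):
            he.frequency_trend([1, 2, 3], [2000, 2001, 2002])

    def test_constant_years_degenerate(self):
        with pytest.raises(he.DegenerateDesignError):
            he.frequency_trend(np.arange(12), np.full(12, 2000))
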