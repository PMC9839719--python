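"""Percentile thresholds and dry/humid heat-day classification.

A station-day is an extreme-Tmax day when its daily maximum dry-bulb
temperature exceeds the station's local percentile threshold (90th or 95th,
computed over a fixed climatological base period, pooled across the season
days of all base years). Days whose daily maximum wet-bulb temperature
exceeds its own threshold are humid heat days; extreme-Tmax days that are
not also humid are dry heat days, so the two classes are disjoint and

    dry + overlap = extreme-Tmax   (conservation)

where overlap counts days exceeding both thresholds. Seasonal exposure is
the per-year count of each class over a configurable month window
(May-September by default, with early/late sub-season splits supported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DRY_HEAT = "DRY_HEAT"
HUMID_HEAT = "HUMID_HEAT"
NONE_LABEL = "NONE"
MISSING = "MISSING"

#: named season windows: extended growing season and its two halves
SEASONS = {
    "MJJAS": (5, 6, 7, 8, 9),
    "MJ": (5, 6),
    "JAS": (7, 8, 9),
}


class ThresholdError(ValueError):
    """Not enough base-period data to estimate a station threshold."""


class DegenerateDesignError(ValueError):
    """Trend regression attempted on a degenerate year axis."""


@dataclass
class StationSeries:
    """Daily weather record for one station.

    ``days`` holds one row per date with columns ``date`` (datetime64),
    ``tmax_c``, ``twmax_c``, ``precip_mm``; missing observations are NaN.
    """

    station_id: str
    lat: float
    lon: float
    elevation_m: float
    days: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.days
        required = {"date", "tmax_c", "twmax_c", "precip_mm"}
        missing = required - set(d.columns)
        if missing:
            raise ValueError(f"StationSeries missing columns: {sorted(missing)}")
        dates = pd.to_datetime(d["date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise ValueError(f"station {self.station_id}: dates must be strictly increasing")
        both = d["tmax_c"].notna() & d["twmax_c"].notna()
        if (d.loc[both, "twmax_c"] > d.loc[both, "tmax_c"] + 1e-9).any():
            raise ValueError(f"station {self.station_id}: twmax_c exceeds tmax_c")
        if (d["precip_mm"].dropna() < 0).any():
            raise ValueError(f"station {self.station_id}: negative precipitation")
        self.days = d.assign(date=dates).reset_index(drop=True)


@dataclass(frozen=True)
class ThresholdSet:
    station_id: str
    level: float
    thr_tmax_c: float
    thr_twmax_c: float
    base_period: tuple[int, int]
    season: tuple[int, ...]
    n_days_used: int


@dataclass(frozen=True)
class SeasonalExposure:
    """Per station-year event counts for one season window."""

    station_id: str
    year: int
    season: tuple[int, ...]
    dhd: int
    hhd: int
    xtmax: int
    overlap: int
    n_days: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.dhd + self.overlap != self.xtmax:
            raise ValueError("exposure counts violate dhd + overlap = xtmax")
        if min(self.dhd, self.hhd, self.xtmax, self.overlap) < 0:
            raise ValueError("negative exposure count")
        if self.hhd < self.overlap:
            raise ValueError("overlap cannot exceed humid-heat count")


@dataclass
class QCReport:
    station_id: str
    passed: bool
    good_month_fraction: float
    month_coverage: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class TrendResult:
    slope_per_year: float
    total_change: float
    p_value: float
    n_years: int


def station_quality_control(
    series: StationSeries,
    period: tuple[int, int],
    months: Sequence[int] | None = None,
    *,
    day_fraction: float = 0.9,
    month_fraction: float = 0.9,
) -> QCReport:
    """Coverage screen: >= 90% of days present in >= 90% of months.

    A month is "good" when at least ``day_fraction`` of its calendar days
    carry a valid tmax observation; the station passes when at least
    ``month_fraction`` of the (year, month) cells in ``period`` are good.
    ``months`` restricts the screen (default: the calendar months present
    in the record, so season-only records are judged over the season).
    """
    d = series.days
    if months is None:
        months = sorted(d["date"].dt.month.unique())
    present = d.loc[d["tmax_c"].notna(), "date"]
    key = present.dt.year * 100 + present.dt.month
    counts = key.value_counts()
    rows = []
    for year in range(period[0], period[1] + 1):
        for month in months:
            n_days = pd.Period(f"{year}-{month:02d}").days_in_month
            n_present = int(counts.get(year * 100 + month, 0))
            rows.append(
                {
                    "year": year,
                    "month": month,
                    "n_days": n_days,
                    "n_present": n_present,
                    "good": n_present / n_days >= day_fraction,
                }
            )
    cov = pd.DataFrame(rows)
    good_frac = float(cov["good"].mean()) if len(cov) else 0.0
    return QCReport(
        station_id=series.station_id,
        passed=good_frac >= month_fraction,
        good_month_fraction=good_frac,
        month_coverage=cov,
    )


def _season_mask(dates: pd.Series, season: Sequence[int]) -> pd.Series:
    return dates.dt.month.isin(list(season))


def compute_thresholds(
    series: StationSeries,
    level: float,
    base_period: tuple[int, int],
    season: Sequence[int] = SEASONS["MJJAS"],
    *,
    min_fraction: float = 0.8,
) -> ThresholdSet:
    """Empirical percentile thresholds over the pooled base-period season days.

    Linear interpolation between closest order statistics; tmax and twmax
    thresholds are computed from their own non-missing samples. Requires at
    least ``min_fraction`` of the possible base-period season days.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    d = series.days
    years = d["date"].dt.year
    in_base = (years >= base_period[0]) & (years <= base_period[1]) & _season_mask(
        d["date"], season
    )
    sub = d.loc[in_base]
    n_possible = _season_days_possible(base_period, season)
    tmax = sub["tmax_c"].dropna().to_numpy()
    twmax = sub["twmax_c"].dropna().to_numpy()
    n_used = min(tmax.size, twmax.size)
    if n_used < min_fraction * n_possible:
        raise ThresholdError(
            f"station {series.station_id}: only {n_used} of {n_possible} "
            f"base-period season days available (need {min_fraction:.0%})"
        )
    return ThresholdSet(
        station_id=series.station_id,
        level=level,
        thr_tmax_c=float(np.percentile(tmax, 100 * level, method="linear")),
        thr_twmax_c=float(np.percentile(twmax, 100 * level, method="linear")),
        base_period=tuple(base_period),
        season=tuple(season),
        n_days_used=int(n_used),
    )


def _season_days_possible(period: tuple[int, int], season: Sequence[int]) -> int:
    total = 0
    for year in range(period[0], period[1] + 1):
        for month in season:
            total += pd.Period(f"{year}-{month:02d}").days_in_month
    return total


def classify_day(tmax_c: float, twmax_c: float, thresholds: ThresholdSet) -> str:
    """Label one day; exceedance is strict ``>``, overlap days count as humid."""
    if pd.isna(tmax_c) or pd.isna(twmax_c):
        return MISSING
    if twmax_c > thresholds.thr_twmax_c:
        return HUMID_HEAT
    if tmax_c > thresholds.thr_tmax_c:
        return DRY_HEAT
    return NONE_LABEL


def classify_days(series: StationSeries, thresholds: ThresholdSet) -> pd.DataFrame:
    """Vectorized labelling of every day in the record.

    Returns ``date, label, exceeds_tmax, exceeds_twmax``; ``exceeds_tmax``
    marks extreme-Tmax days regardless of the humid/dry split.
    """
    d = series.days
    tmax = d["tmax_c"].to_numpy(dtype=float)
    twmax = d["twmax_c"].to_numpy(dtype=float)
    missing = np.isnan(tmax) | np.isnan(twmax)
    ex_t = (tmax > thresholds.thr_tmax_c) & ~missing
    ex_tw = (twmax > thresholds.thr_twmax_c) & ~missing
    labels = np.where(ex_tw, HUMID_HEAT, np.where(ex_t, DRY_HEAT, NONE_LABEL))
    labels = np.where(missing, MISSING, labels)
    return pd.DataFrame(
        {
            "date": d["date"].to_numpy(),
            "label": labels,
            "exceeds_tmax": ex_t,
            "exceeds_twmax": ex_tw,
        }
    )


def seasonal_counts(
    labels: pd.DataFrame,
    station_id: str,
    year: int,
    season: Sequence[int] = SEASONS["MJJAS"],
) -> SeasonalExposure:
    """Count events in one station-year season window.

    Missing days count as non-events; their number is carried so that
    exposures stay comparable across years.
    """
    dates = pd.to_datetime(labels["date"])
    mask = (dates.dt.year == year) & dates.dt.month.isin(list(season))
    sub = labels.loc[mask]
    lab = sub["label"]
    dhd = int((lab == DRY_HEAT).sum())
    hhd = int((lab == HUMID_HEAT).sum())
    xtmax = int(sub["exceeds_tmax"].sum())
    overlap = int((sub["exceeds_tmax"] & sub["exceeds_twmax"]).sum())
    return SeasonalExposure(
        station_id=station_id,
        year=year,
        season=tuple(season),
        dhd=dhd,
        hhd=hhd,
        xtmax=xtmax,
        overlap=overlap,
        n_days=int(len(sub)),
        n_missing=int((lab == MISSING).sum()),
    )


def season_exposures(
    series: StationSeries,
    thresholds: ThresholdSet,
    season: Sequence[int] = SEASONS["MJJAS"],
    years: Sequence[int] | None = None,
) -> list[SeasonalExposure]:
    """Seasonal exposures for every year of the record (or ``years``).

    Vectorized equivalent of calling :func:`seasonal_counts` per year.
    """
    labels = classify_days(series, thresholds)
    dates = pd.DatetimeIndex(labels["date"])
    in_season = np.isin(dates.month, list(season))
    year_arr = dates.year.to_numpy()
    lab = labels["label"].to_numpy()
    ex_t = labels["exceeds_tmax"].to_numpy()
    ex_tw = labels["exceeds_twmax"].to_numpy()
    if years is None:
        years = np.unique(year_arr[in_season]).tolist()
    out = []
    for y in years:
        m = in_season & (year_arr == y)
        out.append(
            SeasonalExposure(
                station_id=series.station_id,
                year=int(y),
                season=tuple(season),
                dhd=int((lab[m] == DRY_HEAT).sum()),
                hhd=int((lab[m] == HUMID_HEAT).sum()),
                xtmax=int(ex_t[m].sum()),
                overlap=int((ex_t[m] & ex_tw[m]).sum()),
                n_days=int(m.sum()),
                n_missing=int((lab[m] == MISSING).sum()),
            )
        )
    return out


def exposures_to_frame(exposures: Sequence[SeasonalExposure]) -> pd.DataFrame:
    """Tabulate exposures: one row per station-year."""
    return pd.DataFrame(
        {
            "station_id": [e.station_id for e in exposures],
            "year": [e.year for e in exposures],
            "dhd": [e.dhd for e in exposures],
            "hhd": [e.hhd for e in exposures],
            "xtmax": [e.xtmax for e in exposures],
            "overlap": [e.overlap for e in exposures],
            "n_days": [e.n_days for e in exposures],
            "n_missing": [e.n_missing for e in exposures],
        }
    )


def overlap_fraction(exposures: Sequence[SeasonalExposure]) -> float:
    """Fraction of extreme-Tmax days also exceeding the wet-bulb threshold.

    Pooled over all years: sum(overlap) / sum(xtmax); NaN (missing, not 0)
    when the station saw no extreme-Tmax days at all.
    """
    total_x = sum(e.xtmax for e in exposures)
    if total_x == 0:
        return float("nan")
    return sum(e.overlap for e in exposures) / total_x


def frequency_trend(counts: Sequence[float], years: Sequence[int]) -> TrendResult:
    """OLS trend of annual event counts: slope, total change, two-sided p.

    Total change = slope * (n_years - 1), the fitted change across the
    record; p from the slope t-test.
    """
    counts = np.asarray(counts, dtype=float)
    years = np.asarray(years, dtype=float)
    if counts.size != years.size:
        raise ValueError("counts and years must align")
    if counts.size < 10:
        raise ValueError(f"need >= 10 years for a trend, got {counts.size}")
    if np.ptp(years) == 0:
        raise DegenerateDesignError("all years identical")
    res = stats.linregress(years, counts)
    return TrendResult(
        slope_per_year=float(res.slope),
        total_change=float(res.slope * (counts.size - 1)),
        p_value=float(res.pvalue),
        n_years=int(counts.size),
    )
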