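"""Yield-sensitivity statistics: detrending, correlations, regressions.

Implements the statistical chain relating county crop yields to seasonal
dry/humid heat-day exposure:

* linear detrending of yearly series (yields and heat-day counts alike),
* Pearson correlation of detrended yield and heat days,
* the per-county multiple regression
      yield*_t = b0 + b1 DHD*_t + b2 HHD*_t
  with plain Student-t significance on coefficient / SE,
* the national fixed-effects panel model on non-detrended yields
      yield_{i,t} = C_i + T_t + b1 DHD_{i,t} + b2 HHD_{i,t}
  with county and year effects absorbing baseline differences and common
  trends,
* the variance inflation factor VIF = 1 / (1 - R^2) between the two
  exposure series, and
* coefficient summaries by latitude band and irrigation group, plus the
  percent-of-mean-yield impact conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

CROPS = ("corn", "soy")


class InsufficientDataError(ValueError):
    pass


class SingularDesignError(ValueError):
    """Perfectly collinear regressors; see variance_inflation for diagnosis."""


@dataclass
class DetrendedSeries:
    """Anomalies after removing an OLS line in year."""

    years: np.ndarray
    anomalies: np.ndarray
    slope: float
    intercept: float

    @property
    def values(self) -> np.ndarray:
        return self.anomalies


@dataclass(frozen=True)
class RegressionResult:
    beta0: float
    beta1: float
    beta2: float
    se: tuple[float, float, float]
    t_stats: tuple[float, float, float]
    p_values: tuple[float, float, float]
    n: int
    r_squared: float
    station_id: str = ""
    county_id: str = ""

    @property
    def beta1_significant(self) -> bool:
        return self.p_values[1] < 0.05

    @property
    def beta2_significant(self) -> bool:
        return self.p_values[2] < 0.05


@dataclass
class PanelFEResult:
    beta1: float
    beta2: float
    se_beta1: float
    se_beta2: float
    p_beta1: float
    p_beta2: float
    county_effects: pd.Series = field(repr=False)
    year_effects: pd.Series = field(repr=False)
    intercept: float = 0.0
    n_obs: int = 0
    n_counties: int = 0
    n_years: int = 0


@dataclass(frozen=True)
class VIFResult:
    r: float
    vif: float


def detrend(years, values) -> DetrendedSeries:
    """Remove the least-squares line in year; anomalies have zero OLS trend."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size != values.size:
        raise ValueError("years and values must align")
    if years.size < 3:
        raise InsufficientDataError(f"need >= 3 years to detrend, got {years.size}")
    if np.unique(years).size != years.size:
        raise ValueError("duplicate years in series")
    slope, intercept = np.polyfit(years, values, 1)
    return DetrendedSeries(
        years=years,
        anomalies=values - (slope * years + intercept),
        slope=float(slope),
        intercept=float(intercept),
    )


def _as_anomalies(x) -> np.ndarray:
    if isinstance(x, DetrendedSeries):
        return x.anomalies
    return np.asarray(x, dtype=float)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r of two (detrended) series and its two-sided Student-t p.

    p uses the t transform with df = n - 2.
    """
    xa, ya = _as_anomalies(x), _as_anomalies(y)
    if xa.size != ya.size or xa.size < 4:
        raise ValueError("series must align with length >= 4")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise InsufficientDataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def fit_yield_regression(
    yield_d, dhd_d, hhd_d, *, station_id: str = "", county_id: str = ""
) -> RegressionResult:
    """OLS of detrended yield on [1, detrended DHD, detrended HHD].

    Significance per coefficient is the plain two-sided Student-t on
    estimate / SE with df = n - 3.
    """
    y = _as_anomalies(yield_d)
    d1 = _as_anomalies(dhd_d)
    d2 = _as_anomalies(hhd_d)
    n = y.size
    if not (d1.size == d2.size == n):
        raise ValueError("series must align")
    if n < 4:
        raise InsufficientDataError(f"need n >= 4, got {n}")
    x = sm.add_constant(np.column_stack([d1, d2]), has_constant="add")
    if np.linalg.matrix_rank(x) < 3:
        raise SingularDesignError(
            "DHD and HHD anomalies are perfectly collinear; "
            "see variance_inflation for the multicollinearity diagnostic"
        )
    fit = sm.OLS(y, x).fit()
    return RegressionResult(
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        beta2=float(fit.params[2]),
        se=tuple(float(s) for s in fit.bse),
        t_stats=tuple(float(t) for t in fit.tvalues),
        p_values=tuple(float(p) for p in fit.pvalues),
        n=int(n),
        r_squared=float(fit.rsquared),
        station_id=station_id,
        county_id=county_id,
    )


def fit_fixed_effects(
    panel: pd.DataFrame,
    exposures: pd.DataFrame,
    *,
    crop: str | None = None,
    non_irrigated_only: bool = True,
    station_county: pd.DataFrame | None = None,
) -> PanelFEResult:
    """Fixed-effects panel model on non-detrended yields.

    ``panel`` rows: county_id, year, yield_bu_acre (optionally crop,
    irrigated); ``exposures`` rows: station-year or county-year dhd/hhd
    counts (a ``station_county`` map with columns station_id, county_id
    joins station exposures to counties). Estimated by OLS with explicit
    county and year indicator columns, dropping one of each (reference
    categories): effects are reported as contrasts.
    """
    df = panel.copy()
    if crop is not None and "crop" in df.columns:
        df = df[df["crop"] == crop]
    if non_irrigated_only and "irrigated" in df.columns:
        df = df[df["irrigated"].astype(int) == 0]
    exp = exposures.copy()
    if "county_id" not in exp.columns:
        if station_county is None:
            raise ValueError("exposures lack county_id and no station_county map given")
        exp = exp.merge(station_county[["station_id", "county_id"]], on="station_id")
    exp = exp.groupby(["county_id", "year"], as_index=False)[["dhd", "hhd"]].mean()
    df = df.merge(exp, on=["county_id", "year"], how="inner")
    counties = sorted(df["county_id"].unique())
    years = sorted(df["year"].unique())
    if len(counties) < 2 or len(years) < 2:
        raise InsufficientDataError("need >= 2 counties and >= 2 years")
    c_dum = pd.get_dummies(df["county_id"], prefix="C", drop_first=True, dtype=float)
    t_dum = pd.get_dummies(df["year"], prefix="T", drop_first=True, dtype=float)
    x = pd.concat(
        [
            pd.Series(1.0, index=df.index, name="const"),
            df[["dhd", "hhd"]].astype(float),
            c_dum,
            t_dum,
        ],
        axis=1,
    )
    fit = sm.OLS(df["yield_bu_acre"].astype(float).to_numpy(), x.to_numpy()).fit()
    params = pd.Series(fit.params, index=x.columns)
    county_effects = pd.Series(
        {counties[0]: 0.0, **{c: params.get(f"C_{c}", 0.0) for c in counties[1:]}}
    )
    year_effects = pd.Series(
        {years[0]: 0.0, **{y: params.get(f"T_{y}", 0.0) for y in years[1:]}}
    )
    bse = pd.Series(fit.bse, index=x.columns)
    pvals = pd.Series(fit.pvalues, index=x.columns)
    return PanelFEResult(
        beta1=float(params["dhd"]),
        beta2=float(params["hhd"]),
        se_beta1=float(bse["dhd"]),
        se_beta2=float(bse["hhd"]),
        p_beta1=float(pvals["dhd"]),
        p_beta2=float(pvals["hhd"]),
        county_effects=county_effects,
        year_effects=year_effects,
        intercept=float(params["const"]),
        n_obs=int(len(df)),
        n_counties=len(counties),
        n_years=len(years),
    )


def variance_inflation(dhd, hhd) -> VIFResult:
    """VIF = 1 / (1 - r^2) between the two exposure count series."""
    x = np.asarray(dhd, dtype=float)
    y = np.asarray(hhd, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must align with length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("zero variance: VIF undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        raise SingularDesignError("|r| = 1: infinite VIF, predictors collinear")
    return VIFResult(r=r, vif=1.0 / (1.0 - r * r))


def _box_summary(values: np.ndarray) -> dict:
    # Tukey box: quartiles, 1.5*IQR whiskers clipped to data, outliers beyond
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "n": int(values.size),
        "mean": float(np.mean(values)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()) if inside.size else float(q1),
        "whisker_hi": float(inside.max()) if inside.size else float(q3),
        "outliers": [float(v) for v in values[(values < lo_fence) | (values > hi_fence)]],
    }


def results_to_frame(results) -> pd.DataFrame:
    """Tabulate per-station regression results (one row per fit)."""
    return pd.DataFrame(
        {
            "station_id": [r.station_id for r in results],
            "county_id": [r.county_id for r in results],
            "beta1": [r.beta1 for r in results],
            "beta2": [r.beta2 for r in results],
            "se_beta1": [r.se[1] for r in results],
            "se_beta2": [r.se[2] for r in results],
            "p_beta1": [r.p_values[1] for r in results],
            "p_beta2": [r.p_values[2] for r in results],
            "n": [r.n for r in results],
            "r_squared": [r.r_squared for r in results],
        }
    )


def summarize_by_latitude(results: pd.DataFrame, band_width: float = 1.0) -> pd.DataFrame:
    """Five-number box summaries of beta1/beta2 per latitude band.

    ``results`` must carry ``lat``, ``beta1``, ``beta2``. Stations are
    assigned to the nearest band centre (integer degrees for the default
    1-degree width); empty bands are omitted.
    """
    if "lat" not in results.columns:
        raise ValueError("results need a 'lat' column")
    band = (np.round(results["lat"] / band_width) * band_width).astype(float)
    rows = []
    for b, grp in results.groupby(band):
        for coef in ("beta1", "beta2"):
            summ = _box_summary(grp[coef].to_numpy(dtype=float))
            summ.update(band=float(b), coefficient=coef)
            rows.append(summ)
    out = pd.DataFrame(rows)
    cols = ["band", "coefficient", "n", "mean", "median", "q1", "q3",
            "whisker_lo", "whisker_hi", "outliers"]
    return out[cols].sort_values(["band", "coefficient"]).reset_index(drop=True)


def summarize_by_group(results: pd.DataFrame) -> pd.DataFrame:
    """Box summaries for irrigated/non-irrigated x dry/humid coefficient groups.

    Both the mean and the median are reported for each group.
    """
    if "irrigated" not in results.columns:
        raise ValueError("results need an 'irrigated' column")
    rows = []
    for irr, grp in results.groupby(results["irrigated"].astype(int)):
        for coef, tag in (("beta1", "dry"), ("beta2", "humid")):
            summ = _box_summary(grp[coef].to_numpy(dtype=float))
            summ.update(group=("Irr" if irr else "Non-Irr") + "/" + tag)
            rows.append(summ)
    out = pd.DataFrame(rows)
    cols = ["group", "n", "mean", "median", "q1", "q3",
            "whisker_lo", "whisker_hi", "outliers"]
    return out[cols].reset_index(drop=True)


def _round_half_away(x: float, decimals: int = 0) -> float:
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_yield_impact(
    beta: float, mean_yield: float, avg_days: float | None = None
) -> tuple[float, float | None]:
    """Convert a Bu/acre-per-day sensitivity into percent of mean yield.

    percent_per_day = 100 * beta / mean_yield, rounded to one decimal;
    cumulative_percent = (unrounded) percent_per_day * avg_days, rounded to
    the nearest whole percent (half away from zero). Returns
    ``(percent_per_day, cumulative_percent)``; the second is None when
    ``avg_days`` is not given.
    """
    if mean_yield <= 0:
        raise ValueError(f"mean_yield must be positive, got {mean_yield}")
    raw_per_day = 100.0 * beta / mean_yield
    per_day = _round_half_away(raw_per_day, 1)
    if avg_days is None:
        return per_day, None
    cumulative = _round_half_away(raw_per_day * avg_days, 0)
    return per_day, cumulative
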