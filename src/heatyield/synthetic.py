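"""Synthetic station weather and county yield panels with planted structure.

Every downstream stage of the pipeline is exercised against data whose
statistical structure is known exactly:

* Daily-maximum dry-bulb temperature = seasonal cycle + AR(1) anomaly.
* Precipitation occurrence from a two-state (wet/dry) chain with
  exponential amounts.
* Daily-maximum wet-bulb temperature = Tmax - depression, where the
  depression shrinks with the rain accumulated over the 3 prior days
  (``humidity_rain_coupling``), so humid-heat days tend to follow rain.
  The depression is floored at zero, so Twmax <= Tmax always.
* County yields = intercept + county offset + technology trend
  + beta1 * dry-heat days + beta2 * humid-heat days + noise, floored at 0.

Each station draws from its own random stream seeded as
``seed XOR station_index``, so stations can be generated independently (and
in parallel) yet reproducibly; the yield panel uses a separate stream
derived from the seed. Identical seed and config give bit-identical output.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SyntheticConfig
from .heat_events import SeasonalExposure, StationSeries, exposures_to_frame

logger = logging.getLogger(__name__)

_SEED_MASK = 0x7FFFFFFF
_YIELD_STREAM_TAG = 0x59E1D


class DataCompletenessError(ValueError):
    """Exposures do not cover every county-year; the message lists the gaps."""


def _season_dates(config: SyntheticConfig) -> pd.DatetimeIndex:
    """All season days of all years, in calendar order."""
    start, end = config.years
    all_days = pd.date_range(f"{start}-01-01", f"{end}-12-31", freq="D")
    return all_days[all_days.month.isin(config.season)]


def _markov_occurrence(u: np.ndarray, p_ww: float, p_wd: float) -> np.ndarray:
    """Two-state wet/dry chain driven by pre-drawn uniforms.

    Day t is wet with probability p_ww (p_wd) given day t-1 wet (dry); the
    first day uses the dry-state probability. For persistent chains
    (p_ww >= p_wd) the state between "forced" draws (u < p_wd: wet
    regardless; u >= p_ww: dry regardless) simply persists, which allows a
    vectorized renewal construction; otherwise a direct loop is used.
    """
    n = u.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    if p_ww >= p_wd:
        forced_wet = u < p_wd
        forced_dry = u >= p_ww
        forced = forced_wet | forced_dry
        idx = np.where(forced, np.arange(n), -1)
        last = np.maximum.accumulate(idx)
        wet = np.where(last >= 0, forced_wet[np.maximum(last, 0)], False)
        # initial state is dry, so unforced leading days stay dry
        return wet
    wet = np.zeros(n, dtype=bool)
    prev = False
    for t in range(n):
        p = p_ww if prev else p_wd
        prev = wet[t] = u[t] < p
    return wet


def _seasonal_cycle(dates: pd.DatetimeIndex, config: SyntheticConfig) -> np.ndarray:
    # annual harmonic peaking mid-July (day of year 196)
    doy = dates.dayofyear.to_numpy()
    return config.temp_mean_c + config.temp_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 196) / 365.25
    )


def _prior3_precip(precip: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Rain summed over the 3 prior days, within each year's season block."""
    out = np.zeros_like(precip)
    for k in (1, 2, 3):
        shifted = np.roll(precip, k)
        shifted[:k] = 0.0
        same_year = np.roll(years, k) == years
        same_year[:k] = False
        out += np.where(same_year, shifted, 0.0)
    return out


def station_location(config: SyntheticConfig, station_index: int) -> tuple[float, float, float]:
    """Deterministic lat/lon/elevation for a station (Corn-Belt-like box)."""
    n = max(config.n_stations - 1, 1)
    lat = 36.0 + 10.0 * station_index / n
    lon = -100.0 + 15.0 * ((station_index * 7) % config.n_stations) / max(config.n_stations, 1)
    elevation = 150.0 + (station_index * 37) % 400
    return lat, lon, float(elevation)


def generate_station_weather(config: SyntheticConfig, station_index: int) -> StationSeries:
    """Generate one station's daily season-day weather record.

    Draws, in a fixed order, from ``default_rng(seed XOR station_index)``:
    temperature innovations, precipitation-occurrence uniforms, exponential
    rain amounts, and wet-bulb-depression noise.
    """
    if not 0 <= station_index < config.n_stations:
        raise ValueError(f"station_index {station_index} outside 0..{config.n_stations - 1}")
    rng = np.random.default_rng((config.seed ^ station_index) & _SEED_MASK)
    dates = _season_dates(config)
    n = len(dates)
    z = rng.standard_normal(n)
    u = rng.random(n)
    amounts = rng.exponential(config.rain_mean_mm, n) if config.rain_mean_mm > 0 else np.zeros(n)
    dep_eps = rng.standard_normal(n)

    # AR(1) anomaly with stationary marginal sd = temp_noise_sd
    innov_sd = config.temp_noise_sd * np.sqrt(1.0 - config.temp_ar1**2)
    anomaly = lfilter([1.0], [1.0, -config.temp_ar1], innov_sd * z)
    tmax = _seasonal_cycle(dates, config) + anomaly

    wet = _markov_occurrence(u, config.rain_prob_wet_after_wet, config.rain_prob_wet_after_dry)
    precip = np.where(wet, amounts, 0.0)
    precip3 = _prior3_precip(precip, dates.year.to_numpy())

    depression = (
        config.wetbulb_depression_mean
        + config.wetbulb_depression_sd * dep_eps
        - config.humidity_rain_coupling * precip3
    )
    twmax = tmax - np.maximum(depression, 0.0)

    lat, lon, elevation = station_location(config, station_index)
    days = pd.DataFrame(
        {"date": dates, "tmax_c": tmax, "twmax_c": twmax, "precip_mm": precip}
    )
    return StationSeries(
        station_id=f"S{station_index:03d}",
        lat=lat,
        lon=lon,
        elevation_m=elevation,
        days=days,
    )


def generate_weather_set(config: SyntheticConfig) -> list[StationSeries]:
    """All stations' records (identical to per-station calls)."""
    return [generate_station_weather(config, i) for i in range(config.n_stations)]


def station_county_map(config: SyntheticConfig) -> pd.DataFrame:
    """Station -> county assignment with the irrigated flag.

    Station i serves county ``i mod n_counties`` (one station per county in
    the default equal-count layout; extra stations wrap around, giving the
    many-stations-per-county mode). The first
    floor(irrigated_fraction * n_counties) counties are flagged irrigated.
    """
    n_irr = int(np.floor(config.irrigated_fraction * config.n_counties))
    rows = []
    for i in range(config.n_stations):
        county = i % config.n_counties
        lat, lon, elevation = station_location(config, i)
        rows.append(
            {
                "station_id": f"S{i:03d}",
                "county_id": f"C{county:03d}",
                "lat": lat,
                "lon": lon,
                "elevation_m": elevation,
                "irrigated": int(county < n_irr),
            }
        )
    return pd.DataFrame(rows)


def generate_yield_panel(
    config: SyntheticConfig,
    exposures: list[SeasonalExposure] | pd.DataFrame,
    *,
    crop: str = "corn",
) -> pd.DataFrame:
    """County-year yields generated from the planted linear response.

    yield_{i,t} = intercept + county_offset_i + trend * (t - t0)
                  + beta1 * DHD_{i,t} + beta2 * HHD_{i,t} + N(0, noise_sd),
    floored at 0 Bu/acre (flooring is logged). Irrigated counties use the
    irrigated sensitivities (zero by default). A county's exposure is its
    assigned station's counts (the lowest-index station when several map to
    the county); a missing county-year raises a completeness error listing
    the gaps.
    """
    exp = exposures if isinstance(exposures, pd.DataFrame) else exposures_to_frame(exposures)
    mapping = station_county_map(config)
    primary = mapping.drop_duplicates("county_id", keep="first")
    exp = exp.merge(primary[["station_id", "county_id", "lat", "irrigated"]], on="station_id")

    years = config.year_list
    counties = sorted(primary["county_id"])
    have = set(zip(exp["county_id"], exp["year"]))
    gaps = [(c, y) for c in counties for y in years if (c, y) not in have]
    if gaps:
        shown = ", ".join(f"{c}:{y}" for c, y in gaps[:10])
        raise DataCompletenessError(
            f"missing exposures for {len(gaps)} county-year(s): {shown}"
            + ("..." if len(gaps) > 10 else "")
        )
    exp = exp[exp["year"].isin(years)].sort_values(["county_id", "year"]).reset_index(drop=True)

    rng = np.random.default_rng([config.seed & _SEED_MASK, _YIELD_STREAM_TAG])
    offsets = dict(zip(counties, rng.normal(0.0, config.county_offset_sd, len(counties))))
    noise = rng.normal(0.0, config.yield_noise_sd, len(exp))

    irr = exp["irrigated"].to_numpy().astype(bool)
    b1 = np.where(irr, config.beta1_true_irrigated, config.beta1_true)
    b2 = np.where(irr, config.beta2_true_irrigated, config.beta2_true)
    t0 = years[0]
    raw = (
        config.yield_intercept
        + exp["county_id"].map(offsets).to_numpy()
        + config.yield_trend * (exp["year"].to_numpy() - t0)
        + b1 * exp["dhd"].to_numpy()
        + b2 * exp["hhd"].to_numpy()
        + noise
    )
    n_floored = int((raw < 0).sum())
    if n_floored:
        logger.info("floored %d negative synthetic yields at 0 Bu/acre", n_floored)
    return pd.DataFrame(
        {
            "county_id": exp["county_id"],
            "year": exp["year"].astype(int),
            "crop": crop,
            "irrigated": exp["irrigated"].astype(int),
            "yield_bu_acre": np.maximum(raw, 0.0),
            "lat": exp["lat"],
        }
    )
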