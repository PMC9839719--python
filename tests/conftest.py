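import numpy as np
import pandas as pd
import pytest

from heatyield import heat_events
from heatyield.config import SyntheticConfig


def bisection_wet_bulb(temp_c: float, q: float, p_hpa: float, iters: int = 60) -> float:
    """Independent oracle: pure bisection on the defining root equation
    theta_e_sat(Tw, p) = theta_e(T, r, p)."""
    from heatyield import wetbulb as wb

    r = q / (1.0 - q)
    r = min(r, wb.saturation_mixing_ratio(p_hpa, temp_c))
    target = wb.equivalent_potential_temperature(temp_c + 273.15, r, p_hpa)
    lo, hi = max(temp_c - 80.0, -59.9), temp_c
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        theta = wb.equivalent_potential_temperature(
            mid + 273.15, wb.saturation_mixing_ratio(p_hpa, mid), p_hpa
        )
        if theta < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_series(
    dates,
    tmax,
    twmax=None,
    precip=None,
    station_id="S000",
    lat=40.0,
    lon=-90.0,
    elevation=200.0,
) -> heat_events.StationSeries:
    """Hand-built station record for fixtures."""
    dates = pd.to_datetime(dates)
    tmax = np.asarray(tmax, dtype=float)
    if twmax is None:
        twmax = tmax - 6.0
    if precip is None:
        precip = np.zeros_like(tmax)
    return heat_events.StationSeries(
        station_id=station_id,
        lat=lat,
        lon=lon,
        elevation_m=elevation,
        days=pd.DataFrame(
            {
                "date": dates,
                "tmax_c": tmax,
                "twmax_c": np.asarray(twmax, dtype=float),
                "precip_mm": np.asarray(precip, dtype=float),
            }
        ),
    )


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Cheap network for end-to-end unit tests."""
    return SyntheticConfig(seed=1, n_stations=4, n_counties=4, years=(1995, 2014),
                           base_period=(1996, 2010))
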