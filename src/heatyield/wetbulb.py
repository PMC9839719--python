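"""Wet-bulb temperature from dry-bulb temperature, specific humidity and pressure.

The wet-bulb temperature Tw is obtained by inverting the pseudoequivalent
potential temperature: Tw is the unique root of

    theta_e(Tw, r_sat(Tw, p), p) = theta_e(T, r, p)

with Tw in [dew point, T]. theta_e follows Bolton's pseudoadiabatic
formulation; the root is located with a Davies-Jones style first guess
(piecewise polynomial in the normalized equivalent temperature) refined by
Newton iteration, with a bracketing fallback when Newton strays. This
inversion is the standard accurate route to Tw at the high temperatures
relevant to heat-extreme work.

Also houses the hourly-to-daily-maximum reduction used when ingesting
hourly station records.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

EPSILON = 0.622          # ratio of gas constants R_d/R_v
KAPPA_D = 0.2854         # Poisson constant for dry air
P_REF_HPA = 1000.0       # reference pressure for potential temperature
T0_K = 273.15

#: lapse-rate constants of the ICAO standard atmosphere used for the
#: sea-level -> station pressure reduction
_STD_LAPSE_K_PER_M = 0.0065
_STD_T0_K = 288.15
_STD_EXPONENT = 5.25588  # g M / (R L)


class DomainError(ValueError):
    """Input outside the physically supported range."""


class ConvergenceError(RuntimeError):
    """Root search for the wet-bulb temperature failed to converge."""

    def __init__(self, temp_c: float, q: float, p_hpa: float, msg: str):
        self.inputs = (temp_c, q, p_hpa)
        super().__init__(f"{msg} (temp_c={temp_c}, q={q}, p_hpa={p_hpa})")


def saturation_vapor_pressure(temp_c: float) -> float:
    """Saturation vapor pressure over water (hPa), Bolton's formula.

    e_s = 6.112 * exp(17.67 * T / (T + 243.5)), T in degrees Celsius.
    Valid for ``temp_c`` in [-60, 60]; strictly increasing and positive.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < -60.0) or np.any(t > 60.0):
        raise DomainError(f"temp_c outside [-60, 60]: {temp_c!r}")
    out = 6.112 * np.exp(17.67 * t / (t + 243.5))
    return float(out) if np.isscalar(temp_c) else out


def saturation_mixing_ratio(p_hpa: float, temp_c: float) -> float:
    """Saturation mixing ratio (kg/kg) at pressure ``p_hpa`` and ``temp_c``."""
    es = saturation_vapor_pressure(temp_c)
    if np.any(np.asarray(es) >= np.asarray(p_hpa)):
        raise DomainError("saturation vapor pressure exceeds total pressure")
    return EPSILON * es / (p_hpa - es)


def specific_humidity_to_mixing_ratio(q: float) -> float:
    """Mixing ratio r = q / (1 - q) from specific humidity q (both kg/kg)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q >= 1):
        raise DomainError(f"specific humidity outside [0, 1): {q!r}")
    out = q / (1.0 - q)
    return float(out) if out.ndim == 0 else out


def relative_humidity_to_q(temp_c: float, rh: float, p_hpa: float) -> float:
    """Specific humidity (kg/kg) from relative humidity in [0, 1]."""
    e = rh * saturation_vapor_pressure(temp_c)
    r = EPSILON * e / (p_hpa - e)
    return r / (1.0 + r)


def station_pressure(slp_hpa: float, elevation_m: float) -> float:
    """Reduce sea-level pressure to station elevation (hPa).

    Uses the ICAO standard-atmosphere relation
    p = slp * (1 - L z / T0)^(gM/RL); equals ``slp_hpa`` at elevation 0.
    """
    z = np.asarray(elevation_m, dtype=float)
    if np.any(z < -100.0) or np.any(z > 4500.0):
        raise DomainError(f"elevation_m outside [-100, 4500]: {elevation_m!r}")
    out = np.asarray(slp_hpa, dtype=float) * (
        1.0 - _STD_LAPSE_K_PER_M * z / _STD_T0_K
    ) ** _STD_EXPONENT
    return float(out) if out.ndim == 0 else out


def _lcl_temperature_k(t_k: float, e_hpa: float) -> float:
    # Bolton's lifting-condensation-level temperature (his eq. for T_L)
    return 2840.0 / (3.5 * math.log(t_k) - math.log(e_hpa) - 4.805) + 55.0


def equivalent_potential_temperature(t_k: float, r: float, p_hpa: float) -> float:
    """Pseudoequivalent potential temperature (K), Bolton's formulation.

    For r = 0 this reduces exactly to the dry potential temperature
    T (1000/p)^kappa. Strictly increasing in ``r`` at fixed ``t_k, p_hpa``.
    """
    if r < 0:
        raise DomainError(f"mixing ratio must be non-negative, got {r}")
    if t_k <= 0 or p_hpa <= 0:
        raise DomainError("temperature and pressure must be positive")
    if r < 1e-12:
        return t_k * (P_REF_HPA / p_hpa) ** KAPPA_D
    e = p_hpa * r / (EPSILON + r)
    t_l = _lcl_temperature_k(t_k, e)
    theta_dl = t_k * (P_REF_HPA / p_hpa) ** (KAPPA_D * (1.0 - 0.28 * r))
    return theta_dl * math.exp((3.376 / t_l - 0.00254) * 1.0e3 * r * (1.0 + 0.81 * r))


def _theta_e_saturated(tw_c: float, p_hpa: float) -> float:
    """theta_e of saturated air at wet-bulb temperature ``tw_c``."""
    rs = saturation_mixing_ratio(p_hpa, tw_c)
    return equivalent_potential_temperature(tw_c + T0_K, rs, p_hpa)


def _first_guess_c(theta_e_k: float, p_hpa: float) -> float:
    """Davies-Jones piecewise first guess for Tw (degrees C).

    Polynomials in x = (C/Te)^3.504 where Te is the equivalent temperature
    at pressure p; the hot branch uses a series expansion around Te.
    """
    teq = theta_e_k * (p_hpa / P_REF_HPA) ** KAPPA_D
    x = (T0_K / teq) ** 3.504
    d_inv = 0.1859 * p_hpa / 1013.25 + 0.6512
    d = 1.0 / d_inv
    k1 = -38.5 * x * x + 137.81 * x - 53.737
    k2 = -4.392 * x * x + 56.831 * x - 0.384
    if x > d:
        teq_c = min(teq - T0_K, 59.0)
        rs = saturation_mixing_ratio(p_hpa, teq_c)
        dlnes_dt = 17.67 * 243.5 / (teq_c + 243.5) ** 2
        return teq_c - 2675.0 * rs / (1.0 + 2675.0 * rs * dlnes_dt)
    if x >= 1.0:
        return k1 - k2 * x
    if x >= 0.4:
        return (k1 - 1.21) - (k2 - 1.21) * x
    return (k1 - 2.66) - (k2 - 1.21) * x + 0.58 / x


def wet_bulb(
    temp_c: float,
    q: float,
    p_hpa: float,
    *,
    tol_k: float = 1e-3,
    max_iter: int = 10,
) -> float:
    """Wet-bulb temperature (degrees C) by inverting theta_e.

    Parameters
    ----------
    temp_c : dry-bulb temperature, degrees C, in [-60, 60].
    q : specific humidity, kg/kg; super-saturated values are clipped to
        saturation with a logged warning.
    p_hpa : station pressure, hPa.
    tol_k : convergence tolerance on the theta_e residual, K.
    max_iter : Newton iteration cap before falling back to bracketing.

    Returns the root Tw of theta_e_sat(Tw, p) = theta_e(T, r, p); Tw <= T
    always, with equality (within numerical tolerance) at saturation.
    """
    if not (-60.0 <= temp_c <= 60.0):
        raise DomainError(f"temp_c outside [-60, 60]: {temp_c}")
    if not (400.0 <= p_hpa <= 1100.0):
        raise DomainError(f"p_hpa outside [400, 1100]: {p_hpa}")
    r = specific_humidity_to_mixing_ratio(q)
    r_sat = saturation_mixing_ratio(p_hpa, temp_c)
    if r > r_sat:
        if r > r_sat * (1.0 + 1e-6):
            logger.warning(
                "super-saturated input clipped to saturation (temp_c=%s, q=%s)", temp_c, q
            )
        r = r_sat
    target = equivalent_potential_temperature(temp_c + T0_K, r, p_hpa)

    def residual(tw_c: float) -> float:
        return _theta_e_saturated(tw_c, p_hpa) - target

    lo = max(temp_c - 80.0, -59.9)
    tw = min(_first_guess_c(target, p_hpa), temp_c)
    tw = max(tw, lo + 1.0)
    h = 1e-3
    converged = False
    for _ in range(max_iter):
        f = residual(tw)
        if abs(f) < tol_k:
            converged = True
            break
        df = (residual(tw + h) - residual(tw - h)) / (2.0 * h)
        if df <= 0 or not math.isfinite(df):
            break
        step = f / df
        tw_new = tw - step
        if not (lo < tw_new <= temp_c + 0.5):
            break
        tw = min(tw_new, temp_c)
    if not converged and abs(residual(tw)) >= tol_k:
        # Newton diverged or stalled: bracketed fallback on the same root
        try:
            tw = brentq(residual, lo, temp_c, xtol=1e-6)
        except ValueError as exc:
            raise ConvergenceError(temp_c, q, p_hpa, "wet-bulb root not bracketed") from exc
        if abs(residual(tw)) >= 10 * tol_k:
            raise ConvergenceError(temp_c, q, p_hpa, "wet-bulb root did not converge")
    return min(tw, temp_c)


def daily_maxima(
    hourly: pd.DataFrame,
    elevation_m: float = 0.0,
    *,
    min_hours: int = 18,
) -> pd.DataFrame:
    """Reduce an hourly record to daily maxima of dry- and wet-bulb temperature.

    Parameters
    ----------
    hourly : DataFrame with columns ``timestamp`` (local civil time, sorted),
        ``temp_c``, ``q_kgkg``, ``slp_hpa``.
    elevation_m : station elevation used to reduce sea-level pressure.
    min_hours : completeness rule; a calendar day with fewer valid hours is
        reported with missing (NaN) maxima, never zero.

    Returns a DataFrame with columns ``date``, ``tmax_c``, ``twmax_c``,
    ``n_hours``. Note the wet-bulb maximum may occur at a different hour
    than the dry-bulb maximum.
    """
    required = {"timestamp", "temp_c", "q_kgkg", "slp_hpa"}
    missing = required - set(hourly.columns)
    if missing:
        raise ValueError(f"hourly frame missing columns: {sorted(missing)}")
    ts = pd.to_datetime(hourly["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("hourly timestamps must be sorted")
    df = hourly.copy()
    df["timestamp"] = ts
    valid = df[["temp_c", "q_kgkg", "slp_hpa"]].notna().all(axis=1)
    df = df.loc[valid]
    p_st = station_pressure(df["slp_hpa"].to_numpy(), elevation_m)
    tw = np.array(
        [
            wet_bulb(t, qq, p)
            for t, qq, p in zip(df["temp_c"].to_numpy(), df["q_kgkg"].to_numpy(), p_st)
        ]
    )
    df = df.assign(tw_c=tw, date=df["timestamp"].dt.date)
    grouped = df.groupby("date")
    out = grouped.agg(
        tmax_c=("temp_c", "max"), twmax_c=("tw_c", "max"), n_hours=("temp_c", "size")
    ).reset_index()
    incomplete = out["n_hours"] < min_hours
    out.loc[incomplete, ["tmax_c", "twmax_c"]] = np.nan
    out["date"] = pd.to_datetime(out["date"])
    return out


def wet_bulb_many(
    temps_c: Iterable[float], qs: Iterable[float], ps_hpa: Iterable[float]
) -> np.ndarray:
    """Element-wise :func:`wet_bulb` over equal-length sequences."""
    return np.array([wet_bulb(t, q, p) for t, q, p in zip(temps_c, qs, ps_hpa)])
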