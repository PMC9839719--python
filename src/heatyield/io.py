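"""CSV dialects for station weather, metadata, yields, and derived tables.

All artifact I/O is plain CSV with a header row; missing values are empty
fields. Round-trips (write then read) are lossless for finite values.
Parse problems are reported with the 1-based file line number (header is
line 1).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .heat_events import SeasonalExposure, StationSeries, ThresholdSet

logger = logging.getLogger(__name__)

HOURLY_COLUMNS = ["station_id", "timestamp", "temp_c", "q_kgkg", "slp_hpa"]
DAILY_COLUMNS = ["station_id", "date", "tmax_c", "twmax_c", "precip_mm"]
METADATA_COLUMNS = ["station_id", "lat", "lon", "elevation_m", "county_id"]
YIELD_COLUMNS = ["county_id", "year", "crop", "irrigated", "yield_bu_acre", "lat"]


class FormatError(ValueError):
    pass


def _check_columns(
    df: pd.DataFrame, required: list[str], path: str, optional: tuple[str, ...] = ()
) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in required and c not in optional]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, unknown)


def _parse_dates(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    bad = parsed.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise FormatError(f"{path}: malformed date {df[col][bad.idxmax()]!r} on line {line}")
    return parsed


def read_daily_csv(path: str | Path) -> pd.DataFrame:
    """Daily station file: station_id, date, tmax_c, twmax_c, precip_mm."""
    df = pd.read_csv(path, dtype={"station_id": str})
    _check_columns(df, DAILY_COLUMNS, str(path))
    df["date"] = _parse_dates(df, "date", str(path))
    return df[DAILY_COLUMNS]


def write_daily_csv(frames: list[StationSeries] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(frames, pd.DataFrame):
        out = frames[DAILY_COLUMNS]
    else:
        parts = [s.days.assign(station_id=s.station_id) for s in frames]
        out = pd.concat(parts, ignore_index=True)[DAILY_COLUMNS]
    out = out.assign(date=pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)


def read_hourly_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str})
    _check_columns(df, HOURLY_COLUMNS, str(path))
    df["timestamp"] = _parse_dates(df, "timestamp", str(path))
    return df[HOURLY_COLUMNS]


def write_hourly_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df[HOURLY_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str, "county_id": str})
    _check_columns(df, METADATA_COLUMNS, str(path), optional=("irrigated",))
    if df["station_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate station_id rows")
    return df[[c for c in df.columns if c in METADATA_COLUMNS + ["irrigated"]]]


def write_metadata_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = METADATA_COLUMNS + (["irrigated"] if "irrigated" in df.columns else [])
    df[cols].to_csv(path, index=False)


def read_yield_csv(path: str | Path) -> pd.DataFrame:
    """County-year yield table; (county, year, crop, irrigated) must be unique."""
    df = pd.read_csv(path, dtype={"county_id": str})
    _check_columns(df, YIELD_COLUMNS, str(path))
    if df.duplicated(["county_id", "year", "crop", "irrigated"]).any():
        raise FormatError(f"{path}: duplicate (county_id, year, crop, irrigated) rows")
    if (df["yield_bu_acre"].dropna() < 0).any():
        raise FormatError(f"{path}: negative yields")
    return df[YIELD_COLUMNS]


def write_yield_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[YIELD_COLUMNS].to_csv(path, index=False)


def station_series_from_frames(
    daily: pd.DataFrame, metadata: pd.DataFrame
) -> list[StationSeries]:
    """Assemble StationSeries objects from the daily + metadata tables."""
    meta = metadata.set_index("station_id")
    out = []
    for sid, grp in daily.groupby("station_id"):
        if sid not in meta.index:
            raise FormatError(f"station {sid} missing from metadata")
        row = meta.loc[sid]
        out.append(
            StationSeries(
                station_id=str(sid),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                elevation_m=float(row["elevation_m"]),
                days=grp[["date", "tmax_c", "twmax_c", "precip_mm"]].reset_index(drop=True),
            )
        )
    return out


def thresholds_to_frame(thresholds: list[ThresholdSet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "station_id": [t.station_id for t in thresholds],
            "level": [t.level for t in thresholds],
            "thr_tmax_c": [t.thr_tmax_c for t in thresholds],
            "thr_twmax_c": [t.thr_twmax_c for t in thresholds],
            "base_start": [t.base_period[0] for t in thresholds],
            "base_end": [t.base_period[1] for t in thresholds],
            "season": ["".join(f"{m:02d}" for m in t.season) for t in thresholds],
            "n_days_used": [t.n_days_used for t in thresholds],
        }
    )


def frame_to_thresholds(df: pd.DataFrame) -> list[ThresholdSet]:
    out = []
    for _, r in df.iterrows():
        season = tuple(int(str(r["season"])[i : i + 2]) for i in range(0, len(str(r["season"])), 2))
        out.append(
            ThresholdSet(
                station_id=str(r["station_id"]),
                level=float(r["level"]),
                thr_tmax_c=float(r["thr_tmax_c"]),
                thr_twmax_c=float(r["thr_twmax_c"]),
                base_period=(int(r["base_start"]), int(r["base_end"])),
                season=season,
                n_days_used=int(r["n_days_used"]),
            )
        )
    return out


def exposures_from_frame(df: pd.DataFrame, season: tuple[int, ...]) -> list[SeasonalExposure]:
    return [
        SeasonalExposure(
            station_id=str(r["station_id"]),
            year=int(r["year"]),
            season=season,
            dhd=int(r["dhd"]),
            hhd=int(r["hhd"]),
            xtmax=int(r["xtmax"]),
            overlap=int(r["overlap"]),
            n_days=int(r["n_days"]),
            n_missing=int(r["n_missing"]),
        )
        for _, r in df.iterrows()
    ]
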