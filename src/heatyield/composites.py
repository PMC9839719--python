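"""Event-relative composites of precipitation and temperature.

For every classified dry-heat or humid-heat day, this module averages
station precipitation over fixed day-offset windows around the event
(default: the 3 days before, the event day, and the 3 days after) and
summarizes event-day Tmax by class. The dry-vs-humid contrast of window
means is tested with a plain two-sample two-sided Student t-test whose
sampling unit is the per-event window mean (not the individual day), which
avoids pseudo-replication inside a window.

Boundary rule: an event near the edge of the record contributes only its
in-range window days; an event whose window is entirely out of range drops
out of that window's composite. Consecutive event days are separate events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .heat_events import DRY_HEAT, HUMID_HEAT, StationSeries

#: day-offset windows relative to the event day
WINDOWS: dict[str, tuple[int, ...]] = {
    "before": (-3, -2, -1),
    "on": (0,),
    "after": (1, 2, 3),
}


@dataclass
class WindowComposite:
    """Composite of one variable over one window for one event class."""

    station_id: str
    event_class: str
    window: str
    mean: float                     # pooled over all (event, in-range day) pairs
    n_events: int                   # events contributing >= 1 in-range day
    per_event_means: np.ndarray = field(repr=False)


@dataclass
class CompositeResult:
    """Per-station summary: precip around events plus event-day Tmax."""

    station_id: str
    event_class: str
    precip_before: float
    precip_on: float
    precip_after: float
    n_events: int
    mean_tmax: float


class NoEventsError(ValueError):
    pass


def _event_windows(
    series: StationSeries, labels: pd.DataFrame, event_class: str, offsets: tuple[int, ...]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-event arrays of in-range window-day precipitation.

    Offsets are applied in calendar days on the record's date index, so a
    window never silently bridges a gap in the record (absent dates are
    simply out of range).
    """
    d = series.days
    index = pd.DatetimeIndex(d["date"])
    precip = d["precip_mm"].to_numpy()
    event_dates = pd.DatetimeIndex(labels.loc[labels["label"] == event_class, "date"])
    n_ev = len(event_dates)
    # one indexer call per offset; -1 marks dates absent from the record
    pos = np.full((n_ev, len(offsets)), -1, dtype=int)
    for j, k in enumerate(offsets):
        pos[:, j] = index.get_indexer(event_dates + pd.Timedelta(days=k))
    per_event: list[np.ndarray] = []
    for i in range(n_ev):
        p = pos[i]
        vals = precip[p[p >= 0]]
        per_event.append(vals[~np.isnan(vals)])
    return event_dates.to_numpy(), per_event


def event_relative_precip(
    series: StationSeries,
    labels: pd.DataFrame,
    event_class: str,
    window: str,
) -> WindowComposite:
    """Mean precipitation (mm/day) over a day-offset window around events.

    The headline mean pools all (event, in-range window-day) pairs; the
    per-event means (used as the t-test sampling unit) are kept alongside.
    Events with no in-range day for this window are excluded from the
    denominator. Windows are allowed to contain other event days.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; choose from {sorted(WINDOWS)}")
    if event_class not in (DRY_HEAT, HUMID_HEAT):
        raise ValueError(f"unsupported event class {event_class!r}")
    _, per_event = _event_windows(series, labels, event_class, WINDOWS[window])
    usable = [v for v in per_event if v.size > 0]
    if not per_event:
        raise NoEventsError(f"no {event_class} events at station {series.station_id}")
    pooled = np.concatenate(usable) if usable else np.array([])
    return WindowComposite(
        station_id=series.station_id,
        event_class=event_class,
        window=window,
        mean=float(pooled.mean()) if pooled.size else float("nan"),
        n_events=len(usable),
        per_event_means=np.array([v.mean() for v in usable]),
    )


def composite_difference(
    dry: WindowComposite, humid: WindowComposite
) -> tuple[float, float]:
    """Humid-minus-dry difference of window means with a two-sided t-test.

    The test is the classic pooled-variance two-sample Student t on the
    per-event window means. Returns ``(difference_mm_per_day, p_value)``;
    p is NaN when either class has fewer than 2 events.
    """
    if dry.window != humid.window:
        raise ValueError("composites are for different windows")
    diff = float(np.mean(humid.per_event_means) - np.mean(dry.per_event_means))
    if dry.per_event_means.size < 2 or humid.per_event_means.size < 2:
        return diff, float("nan")
    _, p = stats.ttest_ind(humid.per_event_means, dry.per_event_means, equal_var=True)
    return diff, float(p)


def mean_tmax_by_class(
    series: StationSeries,
    labels: pd.DataFrame,
    classes: tuple[str, ...] = (DRY_HEAT, HUMID_HEAT),
) -> pd.DataFrame:
    """Event-day Tmax distribution summary per event class.

    One row per class with >= 1 event: mean, median, quartiles, n. Classes
    without events are omitted (missing, never zero-filled).
    """
    d = series.days.set_index(pd.DatetimeIndex(series.days["date"]))
    rows = []
    for cls in classes:
        dates = pd.DatetimeIndex(labels.loc[labels["label"] == cls, "date"])
        tmax = d.loc[d.index.intersection(dates), "tmax_c"].dropna().to_numpy()
        if tmax.size == 0:
            continue
        q1, med, q3 = np.percentile(tmax, [25, 50, 75])
        rows.append(
            {
                "station_id": series.station_id,
                "event_class": cls,
                "mean_tmax": float(tmax.mean()),
                "median_tmax": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "n_events": int(tmax.size),
            }
        )
    return pd.DataFrame(rows)


def station_composites(
    series: StationSeries, labels: pd.DataFrame
) -> list[CompositeResult]:
    """Assemble the before/on/after precip + event-day Tmax summary per class."""
    tmax_summary = mean_tmax_by_class(series, labels)
    out = []
    for cls in (DRY_HEAT, HUMID_HEAT):
        if not (labels["label"] == cls).any():
            continue
        comps = {
            w: event_relative_precip(series, labels, cls, w) for w in WINDOWS
        }
        row = tmax_summary[tmax_summary["event_class"] == cls]
        out.append(
            CompositeResult(
                station_id=series.station_id,
                event_class=cls,
                precip_before=comps["before"].mean,
                precip_on=comps["on"].mean,
                precip_after=comps["after"].mean,
                n_events=comps["on"].n_events,
                mean_tmax=float(row["mean_tmax"].iloc[0]) if len(row) else float("nan"),
            )
        )
    return out
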