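"""Inverse-distance-weighted (IDW) pollutant exposure assignment.

For each residence and anchor date, the daily concentration is the
IDW mean of all monitors within 60 km that report that day:

    c(p, t) = sum_k d_k^-1 x_k / sum_k d_k^-1,

with d_k the haversine distance (km) from the residence to monitor k and
power 1 (plain inverse distance).  A monitor coinciding with the residence
(d = 0) dominates in the limit and its value is returned directly.  The
window exposure is the mean of daily values over the 91 days ending the
day before the anchor; days with no in-radius reading are omitted, and the
estimate is marked missing when the covered fraction falls below a
configurable minimum (default 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "haversine_km",
    "daily_idw",
    "window_average",
    "assign_exposures",
    "NoCoverageError",
    "ExposureEstimate",
]

EARTH_RADIUS_KM = 6371.0088
DEFAULT_RADIUS_KM = 60.0
DEFAULT_WINDOW_DAYS = 91
DEFAULT_MIN_COVERAGE = 0.75


class NoCoverageError(ValueError):
    """No in-radius monitor reported a value for the requested day."""


@dataclass(frozen=True)
class ExposureEstimate:
    participant_id: str
    pollutant: str
    anchor: str
    value: float | None  # ug/m3/day; None when missing
    n_monitor_days: int
    coverage_fraction: float
    missing_reason: str | None = None

    @property
    def missing(self) -> bool:
        return self.value is None


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (mean Earth radius), vectorized."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _monitor_table(monitors: pd.DataFrame) -> pd.DataFrame:
    required = {"monitor_id", "lat", "lon", "date", "pollutant", "value"}
    if not required.issubset(monitors.columns):
        raise ValueError(f"monitor table must have columns {sorted(required)}")
    if not pd.api.types.is_datetime64_any_dtype(monitors["date"]):
        monitors = monitors.assign(date=pd.to_datetime(monitors["date"]))
    return monitors


def daily_idw(
    lat: float,
    lon: float,
    date,
    pollutant: str,
    monitors: pd.DataFrame,
    radius_km: float = DEFAULT_RADIUS_KM,
) -> float:
    """IDW concentration at (lat, lon) on ``date``; raises NoCoverageError."""
    monitors = _monitor_table(monitors)
    date = pd.Timestamp(date)
    day = monitors[(monitors["date"] == date) & (monitors["pollutant"] == pollutant)]
    if day.empty:
        raise NoCoverageError(f"no {pollutant} readings on {date.date()}")
    d = haversine_km(lat, lon, day["lat"].to_numpy(), day["lon"].to_numpy())
    in_radius = d <= radius_km  # inclusive radius test
    if not in_radius.any():
        raise NoCoverageError(
            f"no {pollutant} monitor within {radius_km} km on {date.date()}"
        )
    d = d[in_radius]
    x = day["value"].to_numpy()[in_radius]
    if (d == 0).any():  # co-located monitor: IDW limit as d -> 0
        return float(x[d == 0].mean())
    w = 1.0 / d
    return float((w * x).sum() / w.sum())


def window_average(
    lat: float,
    lon: float,
    anchor_date,
    pollutant: str,
    monitors: pd.DataFrame,
    *,
    participant_id: str = "",
    anchor: str = "",
    radius_km: float = DEFAULT_RADIUS_KM,
    window_days: int = DEFAULT_WINDOW_DAYS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> ExposureEstimate:
    """Mean daily IDW over the ``window_days`` days ending before the anchor.

    The window is half-open: it covers anchor-window_days .. anchor-1 and
    excludes the anchor date itself.
    """
    monitors = _monitor_table(monitors)
    anchor_date = pd.Timestamp(anchor_date)
    days = [anchor_date + pd.Timedelta(days=k) for k in range(-window_days, 0)]
    sub = monitors[monitors["pollutant"] == pollutant]
    sub = sub[(sub["date"] >= days[0]) & (sub["date"] <= days[-1])]
    # restrict to in-radius monitors once, then aggregate per day in numpy
    stations = sub[["monitor_id", "lat", "lon"]].drop_duplicates("monitor_id")
    dist = pd.Series(
        haversine_km(lat, lon, stations["lat"].to_numpy(), stations["lon"].to_numpy()),
        index=stations["monitor_id"].to_numpy(),
    )
    near = dist[dist <= radius_km]  # inclusive radius test
    sub = sub[sub["monitor_id"].isin(near.index)]
    values = []
    if not sub.empty:
        d = near.loc[sub["monitor_id"]].to_numpy()
        x = sub["value"].to_numpy()
        for _, idx in sub.groupby("date").indices.items():
            dk, xk = d[idx], x[idx]
            if (dk == 0).any():  # co-located monitor: IDW limit as d -> 0
                values.append(float(xk[dk == 0].mean()))
            else:
                w = 1.0 / dk
                values.append(float((w * xk).sum() / w.sum()))
    coverage = len(values) / window_days
    if not values:
        return ExposureEstimate(
            participant_id, pollutant, anchor, None, 0, 0.0, "no covered days"
        )
    if coverage < min_coverage:
        return ExposureEstimate(
            participant_id,
            pollutant,
            anchor,
            None,
            len(values),
            coverage,
            "insufficient coverage",
        )
    return ExposureEstimate(
        participant_id, pollutant, anchor, float(np.mean(values)), len(values), coverage
    )


def assign_exposures(
    monitors: pd.DataFrame,
    residences: pd.DataFrame,
    pollutants=("pm25", "pm10"),
    anchors=("birth", "age1", "age3"),
    *,
    radius_km: float = DEFAULT_RADIUS_KM,
    window_days: int = DEFAULT_WINDOW_DAYS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Window-average exposures for every residence x anchor x pollutant.

    ``residences`` needs participant_id, lat, lon and one date column per
    anchor.  Returns a long table with value (NaN when missing),
    n_monitor_days, coverage_fraction and missing_reason.
    """
    monitors = _monitor_table(monitors)
    by_pollutant = {pol: monitors[monitors["pollutant"] == pol] for pol in pollutants}
    records = []
    for _, row in residences.iterrows():
        for anchor in anchors:
            for pol in pollutants:
                est = window_average(
                    row["lat"],
                    row["lon"],
                    row[anchor],
                    pol,
                    by_pollutant[pol],
                    participant_id=row["participant_id"],
                    anchor=anchor,
                    radius_km=radius_km,
                    window_days=window_days,
                    min_coverage=min_coverage,
                )
                records.append(
                    {
                        "participant_id": est.participant_id,
                        "pollutant": est.pollutant,
                        "anchor": est.anchor,
                        "value": np.nan if est.missing else est.value,
                        "n_monitor_days": est.n_monitor_days,
                        "coverage_fraction": est.coverage_fraction,
                        "missing_reason": est.missing_reason or "",
                    }
                )
    return pd.DataFrame.from_records(records)
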