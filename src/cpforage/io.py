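"""Reading and writing GPS fix tables, and calendar helpers.

Fix tables are CSV in the Movebank export dialect by default
(``individual-local-identifier``, ``timestamp``, ``location-lat``,
``location-long``); a column-name mapping lets other dialects in. Timestamps
are parsed as UTC. Austral seasons are assigned from the month of *local*
time, with local time modelled as a fixed UTC offset (default UTC-4, Chilean
mainland standard time; daylight saving is deliberately ignored so that
season boundaries are reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Austral seasons in calendar order starting at the breeding season.
SEASONS = ("summer", "autumn", "winter", "spring")

#: Month-of-local-time -> austral season. Summer is December-February
#: (the kelp-gull breeding season), autumn March-May, winter June-August
#: (post-breeding), spring September-November.
SEASON_OF_MONTH = {
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
    9: "spring", 10: "spring", 11: "spring",
}

#: Default fixed local-time offset from UTC, hours (Chilean standard time).
DEFAULT_TZ_OFFSET_H = -4.0

#: Movebank CSV column names for the canonical fields.
MOVEBANK_DIALECT = {
    "bird_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lat": "location-lat",
    "lon": "location-long",
    "battery_pct": "battery-charge-percent",
}

#: Columns every fix table carries internally.
FIX_COLUMNS = ["timestamp", "lat", "lon", "battery_pct", "flag"]


class DialectError(ValueError):
    """A required column could not be resolved in the input file."""


@dataclass
class Track:
    """One bird's time-ordered GPS fixes.

    ``fixes`` is a DataFrame with columns ``timestamp`` (tz-aware UTC),
    ``lat``, ``lon``, ``battery_pct`` (may be NaN) and ``flag``
    (``ok`` / ``speed_outlier``). Timestamps are strictly increasing.
    """

    bird_id: str
    status: str | None = None  # 'urban' | 'wild' | None
    fixes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FIX_COLUMNS))

    def __post_init__(self):
        f = self.fixes
        if len(f):
            if not f["timestamp"].is_monotonic_increasing:
                raise ValueError(f"track {self.bird_id}: timestamps not increasing")
            lat, lon = f["lat"].to_numpy(float), f["lon"].to_numpy(float)
            if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
                raise ValueError(f"track {self.bird_id}: coordinates out of range")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]


def season_of(timestamp, tz_offset_h: float = DEFAULT_TZ_OFFSET_H) -> str:
    """Austral season of ``timestamp`` (UTC), judged by month of local time."""
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    local = ts + pd.Timedelta(hours=tz_offset_h)
    return SEASON_OF_MONTH[local.month]


def seasons_of(timestamps, tz_offset_h: float = DEFAULT_TZ_OFFSET_H) -> np.ndarray:
    """Vectorised :func:`season_of` for a datetime Series/array."""
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    months = (ts + pd.Timedelta(hours=tz_offset_h)).month
    return np.array([SEASON_OF_MONTH[m] for m in months])


def _make_fix_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sort, de-duplicate and normalise a per-bird raw fix frame."""
    df = df.sort_values("timestamp", kind="stable")
    df = df.drop_duplicates(subset="timestamp", keep="first")
    df = df.reset_index(drop=True)
    df["flag"] = "ok"
    if "battery_pct" not in df.columns:
        df["battery_pct"] = np.nan
    return df[FIX_COLUMNS]


def read_fixes(path, dialect: dict | None = None, statuses: dict | None = None) -> list[Track]:
    """Read a Movebank-style CSV of GPS fixes into one :class:`Track` per bird.

    Parameters
    ----------
    path : str or file
        CSV file with one row per fix.
    dialect : dict, optional
        Mapping canonical field -> column name; merged over the Movebank
        defaults, so only deviations need supplying.
    statuses : dict, optional
        bird_id -> 'urban'/'wild' to attach colony status.

    Rows with missing coordinates are dropped (and counted in the log);
    timestamps are parsed as UTC; rows are time-sorted; duplicate timestamps
    keep the first occurrence.
    """
    cols = dict(MOVEBANK_DIALECT)
    if dialect:
        cols.update(dialect)
    raw = pd.read_csv(path)
    for field_name in ("bird_id", "timestamp", "lat", "lon"):
        if cols[field_name] not in raw.columns:
            raise DialectError(
                f"required column {cols[field_name]!r} (field {field_name}) not in file"
            )
    rename = {v: k for k, v in cols.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # fall back to row-wise parsing to report the offending row
        parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
        bad = np.flatnonzero(parsed.isna() & df["timestamp"].notna())
        raise ValueError(f"unparseable timestamp at row(s) {bad[:5].tolist()}")
    n_before = len(df)
    df = df.dropna(subset=["lat", "lon", "timestamp"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("read_fixes: dropped %d row(s) with missing coordinates/time", n_dropped)
    tracks = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        status = (statuses or {}).get(bird_id)
        tracks.append(Track(str(bird_id), status, _make_fix_frame(grp.copy())))
    return tracks


def write_fixes(tracks, path, dialect: dict | None = None) -> None:
    """Write tracks back to a Movebank-dialect CSV (round-trips read_fixes)."""
    cols = dict(MOVEBANK_DIALECT)
    if dialect:
        cols.update(dialect)
    frames = []
    for tr in tracks:
        out = tr.fixes.copy()
        out["bird_id"] = tr.bird_id
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
        frames.append(out[["bird_id", "timestamp", "lat", "lon", "battery_pct"]])
    all_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["bird_id", "timestamp", "lat", "lon", "battery_pct"]
    )
    all_df = all_df.rename(columns={k: cols[k] for k in all_df.columns})
    all_df.to_csv(path, index=False)


def restrict_period(track: Track, start, end) -> Track:
    """Keep only fixes with start <= t <= end (the study window)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    if end.tzinfo is None:
        end = end.tz_localize("UTC")
    if not start < end:
        raise ValueError("restrict_period: start must precede end")
    f = track.fixes
    keep = f[(f["timestamp"] >= start) & (f["timestamp"] <= end)].reset_index(drop=True)
    if not len(keep):
        logger.warning("restrict_period: track %s has no fixes in window", track.bird_id)
    return replace(track, fixes=keep)
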