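"""GPS track data model and I/O.

A *fix* is one GPS location (bird id, UTC timestamp, lon/lat WGS84); a
*track* is a bird's time-ordered fix sequence. Transmitters in the study
system collect fixes at mixed intervals from 15 minutes to 6 hours, so no
regular sampling is assumed anywhere downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geo import haversine_km as _haversine

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["bird_id", "timestamp", "lon", "lat"]


def haversine_km(a, b) -> float:
    """Great-circle distance in km between two (lon, lat) points."""
    return float(_haversine(a[0], a[1], b[0], b[1]))


@dataclass
class Track:
    """Time-ordered GPS fixes for one bird.

    Stored columnar: `t` is a tz-aware UTC DatetimeIndex-compatible Series,
    `lon`/`lat` float arrays. Timestamps are strictly increasing.
    """

    bird_id: str
    t: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self):
        self.t = pd.DatetimeIndex(self.t)
        if self.t.tz is None:
            self.t = self.t.tz_localize("UTC")
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.t) == len(self.lon) == len(self.lat)):
            raise ValueError("t, lon, lat must have equal length")
        if len(self.t) > 1 and not (np.diff(self.t.asi8) > 0).all():
            raise ValueError(f"track {self.bird_id}: timestamps not strictly increasing")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError(f"track {self.bird_id}: coordinates out of range")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def hours(self) -> np.ndarray:
        """Elapsed hours since the first fix."""
        return (self.t.asi8 - self.t.asi8[0]) / 3.6e12

    def slice(self, mask) -> "Track":
        mask = np.asarray(mask)
        return Track(self.bird_id, self.t[mask], self.lon[mask], self.lat[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bird_id": self.bird_id, "timestamp": self.t, "lon": self.lon, "lat": self.lat}
        )


def read_tracks(path) -> list[Track]:
    """Read tracks from CSV with columns bird_id, timestamp (ISO-8601 UTC), lon, lat.

    Rows are sorted by time per bird; exact-duplicate timestamps within a bird
    are collapsed to the first occurrence (logged). Unparsable rows are
    dropped with a warning giving the count.
    """
    df = pd.read_csv(path, dtype={"bird_id": str})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    n_raw = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    bad = df[["timestamp", "lon", "lat"]].isna().any(axis=1)
    bad |= (df["lat"].abs() > 90) | (df["lon"].abs() > 180)
    if bad.any():
        warnings.warn(f"{path}: skipped {int(bad.sum())} unparsable row(s)", stacklevel=2)
        df = df[~bad]
    df = df.sort_values(["bird_id", "timestamp"], kind="stable")
    dup = df.duplicated(subset=["bird_id", "timestamp"])
    if dup.any():
        logger.info("%s: collapsed %d duplicate-timestamp fix(es)", path, int(dup.sum()))
        df = df[~dup]
    logger.info("%s: %d rows read, %d fixes kept", path, n_raw, len(df))
    return [
        Track(bird, g["timestamp"].to_numpy(), g["lon"].to_numpy(), g["lat"].to_numpy())
        for bird, g in df.groupby("bird_id", sort=True)
    ]


def write_tracks(path, tracks: list[Track]) -> None:
    """Write tracks to the same CSV dialect read_tracks accepts."""
    frames = [t.to_frame() for t in tracks]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    if len(df):
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False)


def fix_speeds(track: Track) -> np.ndarray:
    """Per-fix speed (km/h) attributed to the incoming segment.

    The first fix takes the speed of its outgoing segment; a single-fix track
    yields NaN (undefined). Gaps of any length still yield a speed; over long
    gaps true flight speed is underestimated, which only makes the downstream
    flight filter conservative.
    """
    n = len(track)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([np.nan])
    d = _haversine(track.lon[:-1], track.lat[:-1], track.lon[1:], track.lat[1:])
    dt_h = np.diff(track.t.asi8) / 3.6e12
    seg = d / dt_h
    return np.concatenate([[seg[0]], seg])


def fall_window(track: Track, year: int | None = None) -> Track:
    """Restrict a track to the fall migration window, 1 Aug-31 Dec UTC inclusive.

    `year` defaults to the calendar year of the first fix falling in August
    (any year present in the track); an empty result is returned as a
    zero-length track which callers must exclude downstream.
    """
    if year is None:
        aug = track.t[track.t.month >= 8]
        if len(aug) == 0:
            return track.slice(np.zeros(len(track), dtype=bool))
        year = int(aug[0].year)
    start = pd.Timestamp(year=year, month=8, day=1, tz="UTC")
    end = pd.Timestamp(year=year, month=12, day=31, hour=23, minute=59, second=59, tz="UTC")
    return track.slice((track.t >= start) & (track.t <= end))
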