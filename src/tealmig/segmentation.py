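"""Migration segmentation from net displacement.

The origin is the first fix at/after 1 August; net displacement is the
great-circle distance from that origin to every later fix. Local summer
movement stays within ~50 km of the origin, so migration onset is the moment
a bird leaves that radius without returning, and a bird only counts as a
migrant if it ultimately exceeds 150 km (recursive exploratory flights of up
to ~148 km occur in this system and must not be mistaken for migration).
Departure time is taken midway between the last stationary summer fix and
the first migratory fix. The migration terminus is the southern end of the
route where no further >50 km movements occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geo import haversine_km
from .tracks import Track

#: Radius (km) of local summer movement around the origin.
R_LOCAL_KM = 50.0
#: Minimum ultimate net displacement (km) for a bird to count as a migrant.
R_MIGRANT_KM = 150.0
#: Pre-departure fix gap (h) above which the departure estimate is flagged.
MAX_DEPARTURE_GAP_H = 14.0
#: Minimum residency (days) at the terminus for a migration to be "complete".
MIN_RESIDENCY_DAYS = 7.0


@dataclass
class DepartureEstimate:
    last_summer_fix: int          # index into the track
    first_migratory_fix: int
    departure_time: pd.Timestamp  # midpoint of the bracketing fixes
    reliable: bool = True


@dataclass
class TerminusEstimate:
    terminus_fix: int
    arrival_time: pd.Timestamp
    residency_days: float


@dataclass
class MigrationSegmentation:
    bird_id: str
    origin: tuple[float, float]           # (lon, lat)
    displacement_km: np.ndarray
    is_migrant: bool
    departure: DepartureEstimate | None
    terminus: TerminusEstimate | None
    complete: bool


def net_displacement(track: Track) -> np.ndarray:
    """km from the track's first fix (the August origin) to every fix."""
    if len(track) == 0:
        return np.empty(0)
    return np.asarray(
        haversine_km(track.lon[0], track.lat[0], track.lon, track.lat), dtype=float
    ).reshape(-1)


def classify_migrant(displacement: np.ndarray, r_migrant: float = R_MIGRANT_KM) -> bool:
    """True iff the bird's net displacement ever strictly exceeds r_migrant."""
    return len(displacement) > 0 and float(np.max(displacement)) > r_migrant


def detect_departure(
    track: Track,
    displacement: np.ndarray,
    r_local: float = R_LOCAL_KM,
    max_gap_h: float = MAX_DEPARTURE_GAP_H,
) -> DepartureEstimate:
    """Find migration onset: the last exit from the local radius with no return.

    The first migratory fix is the earliest fix with displacement > r_local
    such that no later fix re-enters the radius; the last summer fix is the
    fix immediately before it. Departure time is their temporal midpoint.
    If the bracketing fixes are more than `max_gap_h` apart the estimate is
    flagged unreliable (large data gaps coinciding with departure make the
    midpoint uninformative).
    """
    outside = displacement > r_local
    if not outside.any():
        raise RuntimeError(f"{track.bird_id}: no fix beyond {r_local} km; not a migrant")
    inside_idx = np.flatnonzero(~outside)
    first_mig = 0 if len(inside_idx) == 0 else int(inside_idx[-1]) + 1
    if first_mig >= len(track) or first_mig == 0:
        raise RuntimeError(
            f"{track.bird_id}: no departure bracket (track starts outside or never leaves)"
        )
    last_summer = first_mig - 1
    t0, t1 = track.t[last_summer], track.t[first_mig]
    gap_h = (t1 - t0).total_seconds() / 3600.0
    return DepartureEstimate(
        last_summer_fix=last_summer,
        first_migratory_fix=first_mig,
        departure_time=t0 + (t1 - t0) / 2,
        reliable=gap_h <= max_gap_h,
    )


def detect_terminus(
    track: Track,
    r_move: float = R_LOCAL_KM,
    min_residency_days: float = MIN_RESIDENCY_DAYS,
) -> TerminusEstimate | None:
    """Terminus = last fix; arrival = earliest time after which the bird
    stays within r_move of it. Returns None if terminal residency is shorter
    than `min_residency_days` (migration end cannot be confirmed; callers
    then use the last known location as the track end)."""
    n = len(track)
    if n == 0:
        return None
    d_end = np.asarray(
        haversine_km(track.lon[-1], track.lat[-1], track.lon, track.lat)
    ).reshape(-1)
    away = np.flatnonzero(d_end > r_move)
    arrival_idx = 0 if len(away) == 0 else int(away[-1]) + 1
    arrival = track.t[arrival_idx]
    residency = (track.t[-1] - arrival).total_seconds() / 86400.0
    if residency < min_residency_days:
        return None
    return TerminusEstimate(terminus_fix=n - 1, arrival_time=arrival, residency_days=residency)


def segment_track(
    track: Track,
    r_local: float = R_LOCAL_KM,
    r_migrant: float = R_MIGRANT_KM,
    max_gap_h: float = MAX_DEPARTURE_GAP_H,
    min_residency_days: float = MIN_RESIDENCY_DAYS,
) -> MigrationSegmentation:
    """Full per-bird segmentation on a fall-windowed track."""
    disp = net_displacement(track)
    migrant = classify_migrant(disp, r_migrant)
    departure = terminus = None
    if migrant:
        departure = detect_departure(track, disp, r_local, max_gap_h)
        terminus = detect_terminus(track, r_local, min_residency_days)
    return MigrationSegmentation(
        bird_id=track.bird_id,
        origin=(float(track.lon[0]), float(track.lat[0])),
        displacement_km=disp,
        is_migrant=migrant,
        departure=departure,
        terminus=terminus,
        complete=terminus is not None,
    )


def segmentation_frame(segs: list[MigrationSegmentation], tracks: list[Track]) -> pd.DataFrame:
    """Tabular summary, one row per bird (the per-bird output CSV schema)."""
    rows = []
    for seg, trk in zip(segs, tracks):
        dep = seg.departure
        rows.append(
            {
                "bird_id": seg.bird_id,
                "is_migrant": seg.is_migrant,
                "departure_time": dep.departure_time.isoformat() if dep else "",
                "departure_doy": int(dep.departure_time.dayofyear) if dep else np.nan,
                "departure_lat": float(trk.lat[dep.last_summer_fix]) if dep else np.nan,
                "terminus_time": seg.terminus.arrival_time.isoformat() if seg.terminus else "",
                "complete": seg.complete,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bird_id", "is_migrant", "departure_time", "departure_doy",
            "departure_lat", "terminus_time", "complete",
        ],
    )
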