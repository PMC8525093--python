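"""Stopover detection from 2-day nearest-neighbor distances.

Nonmigratory movement (resting/foraging, recursive visits within a patch)
keeps relocations close together in space and time, while migratory flight
does not. The per-fix minimum distance to any other fix within a ±48 h
window is therefore bimodal, with a gap at ~5 km: fixes with a neighbor
within 5 km are stopover behavior, the rest are migratory. Fixes moving
faster than 10 km/h are treated as in-flight (ducks swim or walk at no more
than ~5 km/h; median teal flight speed is ~36.5 km/h) and excluded from
habitat "use", and a stopover must contain at least three nonflight fixes
spanning at least three hours. Each site's available-habitat boundary is the
union of 5-km disks around its nonflight use points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from ._geo import LocalProjection, haversine_km
from .tracks import Track, fix_speeds

#: Nearest-neighbor threshold (km) separating stopover from migratory fixes.
NN_THRESHOLD_KM = 5.0
#: Half-width (h) of the temporal neighbor window.
WINDOW_H = 48.0
#: Speed (km/h) above which a fix is classified as in flight.
FLIGHT_SPEED_KMH = 10.0
#: Minimum nonflight fixes per stopover site.
MIN_USE_FIXES = 3
#: Minimum nonflight time span (h) per stopover site.
MIN_SPAN_H = 3.0
#: Buffer radius (km) around use points defining available habitat.
BUFFER_KM = 5.0


@dataclass
class StopoverSite:
    site_id: str
    bird_id: str
    fix_index: np.ndarray            # all member fixes (track indices)
    use_index: np.ndarray            # nonflight member fixes
    arrival_time: pd.Timestamp       # first fix in the site
    departure_time: pd.Timestamp     # last fix in the site
    centroid: tuple[float, float]    # mean lon/lat of use fixes
    polygon: object = None           # shapely polygon in lon/lat (5-km buffer)

    @property
    def arrival_doy(self) -> int:
        return int(self.arrival_time.dayofyear)

    @property
    def n_use_fixes(self) -> int:
        return len(self.use_index)


def nn_distance_2day(track: Track, window_h: float = WINDOW_H) -> np.ndarray:
    """Min distance (km) from each fix to any other fix within ±window_h.

    Fixes with no temporal neighbor get inf. The track must be time-sorted
    (the Track invariant); a two-pointer sweep keeps this O(n·w)."""
    n = len(track)
    out = np.full(n, np.inf)
    if n < 2:
        return out
    t_h = track.t.asi8 / 3.6e12
    lo = 0
    for i in range(n):
        while t_h[i] - t_h[lo] > window_h:
            lo += 1
        hi = i
        while hi + 1 < n and t_h[hi + 1] - t_h[i] <= window_h:
            hi += 1
        idx = np.r_[lo:i, i + 1 : hi + 1]
        if len(idx):
            d = haversine_km(track.lon[i], track.lat[i], track.lon[idx], track.lat[idx])
            out[i] = float(np.min(d))
    return out


def label_fixes(nn_km: np.ndarray, threshold: float = NN_THRESHOLD_KM) -> np.ndarray:
    """True where a fix is stopover behavior (nn distance <= threshold, inclusive)."""
    return np.asarray(nn_km) <= threshold


def flag_flight(speeds: np.ndarray, v_max: float = FLIGHT_SPEED_KMH) -> np.ndarray:
    """True where speed strictly exceeds v_max; undefined (NaN) speeds are not flight."""
    s = np.asarray(speeds, dtype=float)
    with np.errstate(invalid="ignore"):
        return s > v_max


def build_sites(
    track: Track,
    stopover: np.ndarray,
    flying: np.ndarray,
    link_km: float = NN_THRESHOLD_KM,
    link_h: float = WINDOW_H,
) -> list[StopoverSite]:
    """Chain stopover-labeled fixes into candidate sites.

    Greedy temporal chaining: a stopover fix joins the open site iff its gap
    to the site's latest fix is <= link_h AND it lies within link_km of at
    least one fix already in the site; otherwise it starts a new site.
    Flight fixes are excluded from use points but do not break the chain.
    """
    idx = np.flatnonzero(stopover)
    t_h = track.t.asi8 / 3.6e12
    sites_members: list[list[int]] = []
    current: list[int] = []
    for i in idx:
        joins = False
        if current and t_h[i] - t_h[current[-1]] <= link_h:
            mem = np.asarray(current)
            d = haversine_km(track.lon[i], track.lat[i], track.lon[mem], track.lat[mem])
            joins = bool(np.min(d) <= link_km)
        if joins:
            current.append(int(i))
        else:
            if current:
                sites_members.append(current)
            current = [int(i)]
    if current:
        sites_members.append(current)

    sites = []
    for k, members in enumerate(sites_members):
        mem = np.asarray(members)
        use = mem[~flying[mem]]
        ref = use if len(use) else mem
        sites.append(
            StopoverSite(
                site_id=f"{track.bird_id}_s{k:02d}",
                bird_id=track.bird_id,
                fix_index=mem,
                use_index=use,
                arrival_time=track.t[mem[0]],
                departure_time=track.t[mem[-1]],
                centroid=(float(track.lon[ref].mean()), float(track.lat[ref].mean())),
            )
        )
    return sites


def filter_sites(
    candidates: list[StopoverSite],
    track: Track,
    min_use: int = MIN_USE_FIXES,
    min_span_h: float = MIN_SPAN_H,
) -> list[StopoverSite]:
    """Keep sites with >= min_use nonflight fixes spanning >= min_span_h (inclusive)."""
    kept = []
    for s in candidates:
        if s.n_use_fixes < min_use:
            continue
        span_h = (track.t[s.use_index[-1]] - track.t[s.use_index[0]]).total_seconds() / 3600.0
        if span_h >= min_span_h:
            kept.append(s)
    return kept


def buffer_site(site: StopoverSite, track: Track, radius_km: float = BUFFER_KM):
    """5-km geodesic buffer around the site's use points, returned in lon/lat.

    Disks are built in a local azimuthal-equidistant projection centered on
    the site centroid and unioned."""
    proj = LocalProjection(*site.centroid, "aeqd")
    idx = site.use_index if len(site.use_index) else site.fix_index
    x, y = proj.forward(track.lon[idx], track.lat[idx])
    disks = [Point(xi, yi).buffer(radius_km * 1000.0, quad_segs=64) for xi, yi in zip(x, y)]
    return proj.unproject(unary_union(disks))


def detect_stopovers(
    track: Track,
    nn_threshold: float = NN_THRESHOLD_KM,
    window_h: float = WINDOW_H,
    v_max: float = FLIGHT_SPEED_KMH,
    min_use: int = MIN_USE_FIXES,
    min_span_h: float = MIN_SPAN_H,
    buffer_km: float = BUFFER_KM,
) -> list[StopoverSite]:
    """Full stopover detection for one (already windowed/segmented) track."""
    nn = nn_distance_2day(track, window_h)
    stop = label_fixes(nn, nn_threshold)
    fly = flag_flight(fix_speeds(track), v_max)
    sites = filter_sites(build_sites(track, stop, fly, nn_threshold, window_h), track, min_use, min_span_h)
    for s in sites:
        s.polygon = buffer_site(s, track, buffer_km)
    return sites


def sites_frame(sites: list[StopoverSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "bird_id": s.bird_id,
                "arrival_time": s.arrival_time.isoformat(),
                "departure_time": s.departure_time.isoformat(),
                "arrival_doy": s.arrival_doy,
                "n_use_fixes": s.n_use_fixes,
                "centroid_lon": s.centroid[0],
                "centroid_lat": s.centroid[1],
            }
            for s in sites
        ],
        columns=[
            "site_id", "bird_id", "arrival_time", "departure_time",
            "arrival_doy", "n_use_fixes", "centroid_lon", "centroid_lat",
        ],
    )
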