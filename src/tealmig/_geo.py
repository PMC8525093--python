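"""Spherical geometry helpers: great-circle distance, local map projections,
and GeoJSON serialization for shapely geometries.

All projections are spherical (authalic radius 6371.0088 km). At the scales
this package works on (stopover sites a few tens of km across) the error
against ellipsoidal geodesics is well under 0.5%.
"""

from __future__ import annotations

import json
import math
from typing import Iterable

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

#: Mean Earth radius (km), IUGG authalic sphere.
EARTH_RADIUS_KM = 6371.0088

_R_M = EARTH_RADIUS_KM * 1000.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


class LocalProjection:
    """A local projection centered on (lon0, lat0), in meters.

    kind="aeqd"  -- azimuthal equidistant: preserves distance/azimuth from the
                    center; used for buffering and nearest-distance queries.
    kind="laea"  -- Lambert azimuthal equal-area: preserves area; used for all
                    areal availability computations.
    """

    def __init__(self, lon0: float, lat0: float, kind: str = "aeqd"):
        if kind not in ("aeqd", "laea"):
            raise ValueError(f"unknown projection kind {kind!r}")
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.kind = kind
        self._lam0 = math.radians(lon0)
        self._phi0 = math.radians(lat0)

    # -- forward / inverse on coordinate arrays ------------------------------
    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        sin0, cos0 = math.sin(self._phi0), math.cos(self._phi0)
        cosc = sin0 * np.sin(phi) + cos0 * np.cos(phi) * np.cos(dlam)
        cosc = np.clip(cosc, -1.0, 1.0)
        if self.kind == "aeqd":
            c = np.arccos(cosc)
            with np.errstate(invalid="ignore", divide="ignore"):
                k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        else:  # laea
            k = np.sqrt(2.0 / np.maximum(1e-12, 1.0 + cosc))
        x = _R_M * k * np.cos(phi) * np.sin(dlam)
        y = _R_M * k * (cos0 * np.sin(phi) - sin0 * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / _R_M
        y = np.asarray(y, dtype=float) / _R_M
        rho = np.hypot(x, y)
        sin0, cos0 = math.sin(self._phi0), math.cos(self._phi0)
        if self.kind == "aeqd":
            c = rho
        else:
            c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        sinc, cosc = np.sin(c), np.cos(c)
        safe = rho > 1e-12
        rho_s = np.where(safe, rho, 1.0)
        phi = np.arcsin(np.clip(cosc * sin0 + np.where(safe, y * sinc * cos0 / rho_s, 0.0), -1.0, 1.0))
        lam = self._lam0 + np.arctan2(x * sinc, rho_s * cosc * cos0 - y * sinc * sin0)
        lam = np.where(safe, lam, self._lam0)
        phi = np.where(safe, phi, self._phi0)
        return np.degrees(lam), np.degrees(phi)

    # -- geometry transforms -------------------------------------------------
    def project(self, geom: BaseGeometry) -> BaseGeometry:
        """lon/lat geometry -> local meters."""
        return shapely.transform(geom, lambda pts: np.column_stack(self.forward(pts[:, 0], pts[:, 1])))

    def unproject(self, geom: BaseGeometry) -> BaseGeometry:
        """local meters -> lon/lat geometry."""
        return shapely.transform(geom, lambda pts: np.column_stack(self.inverse(pts[:, 0], pts[:, 1])))


def geodesic_area_m2(geom: BaseGeometry, lon0: float | None = None, lat0: float | None = None) -> float:
    """Area of a lon/lat polygon in m², via a local equal-area projection."""
    if geom.is_empty:
        return 0.0
    if lon0 is None or lat0 is None:
        c = geom.centroid
        lon0, lat0 = c.x, c.y
    return LocalProjection(lon0, lat0, "laea").project(geom).area


# -- GeoJSON -----------------------------------------------------------------

def write_geojson(path, geoms: Iterable[BaseGeometry], properties: Iterable[dict]) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path):
    """Return (geometries, properties) lists from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    geoms, props = [], []
    for feat in gj["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props
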