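"""Geographic primitives on a spherical Earth.

All distance rules in the analysis (residence clustering, site linkage,
neighbourhoods) use great-circle distance on raw latitude/longitude.
Planar coordinates from the azimuthal equidistant (AEQD) projection are
used only for the distance-from-breeding-grounds response, which is how
the site-distance metric is defined.

Earth model: sphere with the IUGG mean radius, 6371.0088 km.  Within the
study region (roughly 28-45 deg N, 95-80 deg W) the spherical/ellipsoidal
discrepancy is below 0.5%, which is immaterial against 10 km thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM: float = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "centroid",
    "greatcircle_km",
    "haversine_km",
    "project_aeqd",
    "destination_point",
]


@dataclass(frozen=True)
class GeoPoint:
    """A point on the globe in decimal degrees (WGS84-style lat/lon order).

    Parameters
    ----------
    lat : float
        Latitude, degrees north, in [-90, 90].
    lon : float
        Longitude, degrees east, in [-180, 180].
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat!r} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon!r} outside [-180, 180]")


def centroid(points: list[GeoPoint]) -> GeoPoint:
    """Arithmetic-mean centroid of a set of coordinates.

    Adequate for point sets spanning a few degrees (the summer pen
    locations span well under 2 degrees); no longitude wraparound is
    attempted and inputs spanning more than 90 degrees of longitude are
    rejected.

    Raises
    ------
    ValueError
        If ``points`` is empty or the longitude span exceeds 90 degrees.
    """
    if len(points) == 0:
        raise ValueError("centroid of an empty point set is undefined")
    lons = [p.lon for p in points]
    if max(lons) - min(lons) > 90.0:
        raise ValueError(
            "longitude span exceeds 90 degrees; arithmetic averaging invalid"
        )
    return GeoPoint(
        lat=float(np.mean([p.lat for p in points])),
        lon=float(np.mean(lons)),
    )


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between coordinate arrays (broadcasting)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards tiny negative/over-1 values from rounding
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def greatcircle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two :class:`GeoPoint` in km."""
    return float(haversine_km(a.lat, a.lon, b.lat, b.lon))


def project_aeqd(lat, lon, centre: GeoPoint):
    """Forward azimuthal equidistant projection, spherical form.

    Returns ``(x, y)`` in kilometres east/north of ``centre``.  Distances
    from the projection centre are preserved exactly; distances between
    two off-centre points are distorted by at most the tangential scale
    factor ``c/sin(c)`` (about 1% at 1,600 km from the centre).

    Accepts scalars or arrays (broadcasting).

    Raises
    ------
    ValueError
        For points antipodal to the centre (projection singularity).
    """
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    lat0 = math.radians(centre.lat)
    lon0 = math.radians(centre.lon)

    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    if np.any(c > math.pi - 1e-9):
        raise ValueError("point antipodal to projection centre: AEQD undefined")
    # k = c / sin(c), with the removable singularity at c == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c < 1e-12, 1.0, c / np.sin(np.where(c < 1e-12, 1.0, c)))
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lon0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0)
    )
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def aeqd_distance_km(lat, lon, centre: GeoPoint):
    """Planar AEQD distance from ``centre`` (equals great-circle by construction)."""
    x, y = project_aeqd(lat, lon, centre)
    return np.hypot(x, y)


def destination_point(origin: GeoPoint, bearing_deg: float, distance_km: float) -> GeoPoint:
    """Point reached from ``origin`` travelling ``distance_km`` along ``bearing_deg``.

    Spherical direct geodesic; bearing measured clockwise from north.
    """
    delta = distance_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    phi1 = math.radians(origin.lat)
    lam1 = math.radians(origin.lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon = math.degrees(lam2)
    lon = (lon + 180.0) % 360.0 - 180.0
    return GeoPoint(lat=math.degrees(phi2), lon=lon)
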