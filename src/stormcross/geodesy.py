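"""Great-circle geometry primitives shared by every pipeline stage.

All coordinates are geographic degrees (lat in [-90, 90], lon in [-180, 180)).
Internally positions are handled as Earth-centred unit vectors, so longitude
arithmetic never wraps and the antimeridian needs no special casing.  The
sphere radius defaults to the IUGG mean radius; at basin scale the difference
from an ellipsoid is well under half a percent and irrelevant next to fix
noise and six-hourly storm sampling.

The one domain-specific primitive is :func:`crossing_time`: the boundary
crossing instant between an outside fix and an inside fix is interpolated at
a fixed mean flight speed (the cohort-mean in-flight ground speed, default
14.8 m/s), i.e. ``t_cross = t_outside + d / v`` where ``d`` is the
great-circle distance from the outside fix to the first boundary crossing
along the segment.  A proportional (linear-in-time) alternative is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
from shapely.geometry import LineString
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius
MEAN_FLIGHT_SPEED_MS = 14.8  # cohort-mean in-flight ground speed


@dataclass(frozen=True)
class GeoParams:
    """Shared geometric constants.

    earth_radius_km : sphere radius used for all distances, km.
    mean_flight_speed : fixed ground speed used to interpolate boundary
        crossing times, m/s.
    interpolation : 'fixed_speed' (default) or 'proportional'
        (linear-in-time between the bracketing fixes).
    """

    earth_radius_km: float = EARTH_RADIUS_KM
    mean_flight_speed: float = MEAN_FLIGHT_SPEED_MS
    interpolation: str = "fixed_speed"

    def __post_init__(self) -> None:
        if self.earth_radius_km <= 0:
            raise ValueError("earth_radius_km must be positive")
        if self.mean_flight_speed <= 0:
            raise ValueError("mean_flight_speed must be positive")
        if self.interpolation not in ("fixed_speed", "proportional"):
            raise ValueError(f"unknown interpolation mode {self.interpolation!r}")


DEFAULT_PARAMS = GeoParams()


def ll_to_vec(lat, lon):
    """Degrees -> unit vector(s), shape (..., 3)."""
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    cl = np.cos(lat)
    return np.stack([cl * np.cos(lon), cl * np.sin(lon), np.sin(lat)], axis=-1)


def vec_to_ll(v):
    """Unit vector(s) -> (lat, lon) degrees with lon in [-180, 180)."""
    v = np.asarray(v, dtype=float)
    lat = np.rad2deg(np.arctan2(v[..., 2], np.hypot(v[..., 0], v[..., 1])))
    lon = np.rad2deg(np.arctan2(v[..., 1], v[..., 0]))
    lon = np.where(lon >= 180.0, lon - 360.0, lon)
    return lat, lon


def _check_coords(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("non-finite coordinate")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon < -180.0) | (lon > 360.0)):
        raise ValueError("longitude out of range")


def gc_distance(p1, p2, params: GeoParams = DEFAULT_PARAMS) -> float:
    """Great-circle distance in km between (lat, lon) pairs.

    Uses the atan2 form of the haversine, which is accurate for both tiny
    and near-antipodal separations.
    """
    lat1, lon1 = p1
    lat2, lon2 = p2
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    v1 = ll_to_vec(lat1, lon1)
    v2 = ll_to_vec(lat2, lon2)
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    ang = np.arctan2(cross, dot)
    return float(ang) * params.earth_radius_km if np.ndim(ang) == 0 else ang * params.earth_radius_km


def initial_bearing(p1, p2) -> float:
    """Initial great-circle bearing from p1 to p2, degrees in [0, 360).

    0 = due north, clockwise positive. Raises on coincident points.
    """
    lat1, lon1 = p1
    lat2, lon2 = p2
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    if gc_distance(p1, p2) < 1e-12:
        raise ValueError("bearing undefined for coincident points")
    f1, f2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dl = np.deg2rad(lon2 - lon1)
    y = np.sin(dl) * np.cos(f2)
    x = np.cos(f1) * np.sin(f2) - np.sin(f1) * np.cos(f2) * np.cos(dl)
    return float(np.rad2deg(np.arctan2(y, x)) % 360.0)


def destination_point(p, bearing_deg: float, distance_km: float,
                      params: GeoParams = DEFAULT_PARAMS):
    """Point reached from p after distance_km on initial bearing (degrees)."""
    lat, lon = p
    _check_coords(lat, lon)
    d = distance_km / params.earth_radius_km
    th = np.deg2rad(bearing_deg)
    f1 = np.deg2rad(lat)
    l1 = np.deg2rad(lon)
    f2 = np.arcsin(np.sin(f1) * np.cos(d) + np.cos(f1) * np.sin(d) * np.cos(th))
    l2 = l1 + np.arctan2(np.sin(th) * np.sin(d) * np.cos(f1),
                         np.cos(d) - np.sin(f1) * np.sin(f2))
    lat2 = float(np.rad2deg(f2))
    lon2 = float((np.rad2deg(l2) + 540.0) % 360.0 - 180.0)
    return lat2, lon2


def slerp(p1, p2, frac):
    """Point(s) a fraction of the way along the great circle p1 -> p2."""
    v1 = ll_to_vec(*p1)
    v2 = ll_to_vec(*p2)
    dot = np.clip(np.dot(v1, v2), -1.0, 1.0)
    omega = np.arccos(dot)
    frac = np.asarray(frac, dtype=float)
    if omega < 1e-12:
        v = np.broadcast_to(v1, frac.shape + (3,)) if frac.ndim else v1
        return vec_to_ll(v)
    so = np.sin(omega)
    a = np.sin((1.0 - frac) * omega) / so
    b = np.sin(frac * omega) / so
    v = a[..., None] * v1 + b[..., None] * v2 if frac.ndim else a * v1 + b * v2
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return vec_to_ll(v)


def _as_tp(p):
    """Accept a TrackPoint-like object or a (timestamp, lat, lon) tuple."""
    if hasattr(p, "timestamp"):
        return p.timestamp, p.lat, p.lon
    t, lat, lon = p
    return t, lat, lon


def interpolate_position(track_points: Sequence, t: datetime):
    """Position at instant t along a time-sorted sequence of fixes.

    Interpolates on the great-circle segment between the bracketing fixes,
    with fraction proportional to elapsed time.  Exact at the knots.
    Raises if t is outside the track's time span.
    """
    pts = [_as_tp(p) for p in track_points]
    if not pts:
        raise ValueError("empty track")
    times = [p[0] for p in pts]
    if t < times[0] or t > times[-1]:
        raise ValueError(f"instant {t} outside track span [{times[0]}, {times[-1]}]")
    # binary search for the bracketing pair
    lo = int(np.searchsorted(np.array(times, dtype="datetime64[us]"),
                             np.datetime64(t, "us"), side="right")) - 1
    lo = max(0, min(lo, len(pts) - 2)) if len(pts) > 1 else 0
    t0, lat0, lon0 = pts[lo]
    if len(pts) == 1 or t == t0:
        return float(lat0), float(lon0)
    t1, lat1, lon1 = pts[lo + 1]
    span = (t1 - t0).total_seconds()
    frac = 0.0 if span == 0 else (t - t0).total_seconds() / span
    lat, lon = slerp((lat0, lon0), (lat1, lon1), float(frac))
    return float(lat), float(lon)


def path_length(track_points: Sequence, params: GeoParams = DEFAULT_PARAMS) -> float:
    """Sum of great-circle distances over consecutive fixes, km."""
    pts = [_as_tp(p) for p in track_points]
    if len(pts) < 2:
        raise ValueError("path_length needs at least 2 points")
    total = 0.0
    for (t0, la0, lo0), (t1, la1, lo1) in zip(pts[:-1], pts[1:]):
        total += gc_distance((la0, lo0), (la1, lo1), params)
    return total


def _densify_segment(p1, p2, n: int = 256):
    fr = np.linspace(0.0, 1.0, n)
    lat, lon = slerp(p1, p2, fr)
    return np.column_stack([lon, lat])


def first_boundary_crossing(p_out, p_in, boundary: BaseGeometry, n: int = 256):
    """First crossing of the great-circle segment p_out -> p_in with a boundary.

    The segment is densified to n vertices in lon/lat; shapely finds the
    intersections with the boundary (a polyline, ring, or polygon exterior).
    Returns ((lat, lon), n_crossings). Raises if the segment never crosses.
    """
    if boundary.geom_type in ("Polygon", "MultiPolygon"):
        boundary = boundary.boundary
    seg = LineString(_densify_segment(p_out, p_in, n))
    inter = seg.intersection(boundary)
    if inter.is_empty:
        raise ValueError("segment does not cross the boundary")
    if inter.geom_type == "Point":
        cands = [inter]
    elif hasattr(inter, "geoms"):
        cands = [g for g in inter.geoms if g.geom_type == "Point"]
        if not cands:  # overlap along the boundary: take representative points
            cands = [g.representative_point() for g in inter.geoms]
    else:
        cands = [inter.representative_point()]
    # order by distance along the segment from the outside end
    cands = sorted(cands, key=lambda g: seg.project(g))
    n_cross = len(cands)
    if n_cross > 1:
        logger.debug("segment crosses boundary %d times; using first", n_cross)
    first = cands[0]
    return (first.y, first.x), n_cross


def crossing_time(outside_point, inside_point, boundary: BaseGeometry,
                  params: GeoParams = DEFAULT_PARAMS) -> datetime:
    """Instant at which the moving animal crossed the boundary.

    fixed_speed mode (default): the crossing instant is the outside fix's
    timestamp plus d / v, with d the great-circle distance from the outside
    fix to the first boundary crossing along the segment and v the fixed
    mean flight speed.  If d / v overshoots the fix gap the result is
    clamped to the inside fix's timestamp with a warning.

    proportional mode: linear-in-time at the crossing's along-segment
    fraction.
    """
    t_out, lat_out, lon_out = _as_tp(outside_point)
    t_in, lat_in, lon_in = _as_tp(inside_point)
    (clat, clon), n_cross = first_boundary_crossing(
        (lat_out, lon_out), (lat_in, lon_in), boundary)
    if n_cross > 1:
        logger.info("multiple boundary crossings (%d); first used", n_cross)
    d_km = gc_distance((lat_out, lon_out), (clat, clon), params)
    if params.interpolation == "proportional":
        total = gc_distance((lat_out, lon_out), (lat_in, lon_in), params)
        frac = 0.0 if total == 0 else d_km / total
        return t_out + (t_in - t_out) * frac
    dt = timedelta(seconds=d_km * 1000.0 / params.mean_flight_speed)
    t_cross = t_out + dt
    gap = t_in - t_out
    if dt > gap:
        warnings.warn(
            "fixed-speed crossing time exceeds the fix gap; clamped to the "
            "inside fix's timestamp", stacklevel=2)
        return t_in
    return t_cross
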