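"""Segment annual tracks into phases and summarise journeys.

A journey is segmented into stationary phases (breeding territory, staging
sites, winter territory) and movement in between.  Stationarity is
operationalised as a maximal run of fixes that all stay within a fixed radius
(default 50 km) of the run's centroid for at least a minimum dwell time
(default 7 days); the first such phase is the breeding territory and the last
the winter territory.  Departure is the last fix inside the breeding radius
before a sustained displacement (no return within the dwell window), which
also guards against "false starts".

The trans-oceanic leg is delimited by the two coast crossings.  Because fixes
arrive on a transmitter duty cycle, the actual coast-crossing instants are
interpolated at the cohort-mean flight speed: the departure instant is the
first over-water fix's time minus (distance from that fix back to the coast) /
v, and the arrival instant is the last over-water fix's time plus (distance
on to the coast) / v.  Flight length is the fix-to-fix great-circle path over
water plus the two coast stubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.geometry import Point

from .formats_io import BirdTrack
from .geodesy import (DEFAULT_PARAMS, GeoParams, first_boundary_crossing,
                      gc_distance, ll_to_vec, path_length, vec_to_ll)

logger = logging.getLogger(__name__)

MAX_PLAUSIBLE_SPEED_MS = 30.0  # sanity ceiling for sustained flight


class SegmentationError(ValueError):
    """Track cannot be segmented into the expected phases."""


@dataclass
class Phase:
    kind: str                    # breeding | staging | transoceanic | winter | transit
    start: datetime
    end: datetime
    centroid: tuple[float, float]  # (lat, lon)
    indices: list[int]
    radius_km: float | None = None

    @property
    def duration_days(self) -> float:
        return (self.end - self.start).total_seconds() / 86400.0


@dataclass
class JourneySummary:
    bird_id: str
    population: str | None
    year: int
    departure_date: datetime
    arrival_date: datetime
    total_distance: float        # km
    duration: float              # days
    rate_of_advance: float       # km/day
    ocean_departure_lat: float | None = None
    ocean_flight_length: float | None = None   # km
    ocean_flight_duration: float | None = None  # days
    grounded: bool = False


@dataclass
class Coastlines:
    """Land polygons (lon/lat) for the two continents bracketing the ocean."""

    north: BaseGeometry
    south: BaseGeometry
    islands: BaseGeometry | None = None

    def on_land(self, lat: float, lon: float) -> bool:
        pt = Point(lon, lat)
        if self.north.contains(pt) or self.south.contains(pt):
            return True
        return bool(self.islands is not None and self.islands.contains(pt))


def _centroid(vecs: np.ndarray) -> tuple[float, float]:
    m = vecs.mean(axis=0)
    m /= np.linalg.norm(m)
    lat, lon = vec_to_ll(m)
    return float(lat), float(lon)


def detect_residency(track: BirdTrack, radius_km: float = 50.0,
                     min_days: float = 7.0) -> list[Phase]:
    """Maximal stationary intervals: all fixes within radius of the running
    centroid, lasting at least min_days."""
    pts = track.points
    n = len(pts)
    if n == 0:
        raise SegmentationError("empty track")
    vecs = ll_to_vec([p.lat for p in pts], [p.lon for p in pts])
    ang_radius = radius_km / DEFAULT_PARAMS.earth_radius_km
    cos_thresh = np.cos(ang_radius)

    phases: list[Phase] = []
    i = 0
    while i < n:
        j = i
        # grow while every fix in [i, j] stays within radius of the centroid
        while j + 1 < n:
            window = vecs[i:j + 2]
            c = window.mean(axis=0)
            c /= np.linalg.norm(c)
            if np.min(window @ c) < cos_thresh:
                break
            j += 1
        dur = (pts[j].timestamp - pts[i].timestamp).total_seconds() / 86400.0
        if j > i and dur >= min_days and radius_km > 0:
            phases.append(Phase("staging", pts[i].timestamp, pts[j].timestamp,
                                _centroid(vecs[i:j + 1]), list(range(i, j + 1)),
                                radius_km))
            i = j + 1
        else:
            i += 1
    if phases:
        phases[0].kind = "breeding"
        if len(phases) > 1:
            phases[-1].kind = "winter"
    return phases


def detect_departure_arrival(phases: list[Phase], track: BirdTrack,
                             min_days: float = 7.0
                             ) -> tuple[datetime, datetime]:
    """Departure from the breeding territory and arrival on winter territory.

    Departure: timestamp of the last fix inside the breeding radius before a
    displacement beyond twice the radius with no return within min_days
    (returns are logged as false starts and skipped).  Arrival: first fix
    within the winter phase's radius of its centroid.
    """
    breeding = next((p for p in phases if p.kind == "breeding"), None)
    winter = next((p for p in phases if p.kind == "winter"), None)
    if breeding is None or winter is None:
        raise SegmentationError("need identified breeding and winter phases")
    pts = track.points
    radius = breeding.radius_km or 50.0

    def dist_to(centroid, p):
        return gc_distance(centroid, (p.lat, p.lon))

    start_idx = breeding.indices[0]
    k = start_idx
    departure = None
    while k < len(pts):
        if dist_to(breeding.centroid, pts[k]) > 2.0 * radius:
            # candidate departure: check for a return within min_days
            t_limit = pts[k].timestamp + timedelta(days=min_days)
            ret = next((m for m in range(k + 1, len(pts))
                        if pts[m].timestamp <= t_limit
                        and dist_to(breeding.centroid, pts[m]) <= radius), None)
            if ret is not None:
                logger.warning("bird %s: false start at %s (returned by %s)",
                               track.bird_id, pts[k].timestamp,
                               pts[ret].timestamp)
                k = ret + 1
                continue
            prior = [m for m in range(start_idx, k)
                     if dist_to(breeding.centroid, pts[m]) <= radius]
            if not prior:
                raise SegmentationError("no territorial fix before departure")
            departure = pts[prior[-1]].timestamp
            break
        k += 1
    if departure is None:
        raise SegmentationError(f"bird {track.bird_id}: no departure detected")

    wradius = winter.radius_km or 50.0
    arrival = next((p.timestamp for p in pts
                    if p.timestamp > departure
                    and dist_to(winter.centroid, p) <= wradius), None)
    if arrival is None:
        raise SegmentationError(f"bird {track.bird_id}: no winter arrival")
    return departure, arrival


def segment_transoceanic(track: BirdTrack, coastlines: Coastlines,
                         params: GeoParams = DEFAULT_PARAMS
                         ) -> tuple[Phase, dict]:
    """Find the ocean crossing and its interpolated bounds and length.

    Returns the transoceanic Phase and a metrics dict with keys
    departure_time, arrival_time, duration_days, length_km, departure_lat,
    plus a speed-sanity flag.
    """
    pts = track.points
    over_water = [not coastlines.on_land(p.lat, p.lon) for p in pts]

    # candidate runs of consecutive over-water fixes flanked by the two coasts
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(pts)
    while i < n:
        if over_water[i]:
            j = i
            while j + 1 < n and over_water[j + 1]:
                j += 1
            prev_north = i > 0 and coastlines.north.contains(
                Point(pts[i - 1].lon, pts[i - 1].lat))
            next_south = j + 1 < n and coastlines.south.contains(
                Point(pts[j + 1].lon, pts[j + 1].lat))
            if prev_north and next_south:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        raise SegmentationError(
            f"bird {track.bird_id}: no over-water run between the coasts")
    # take the longest crossing by over-water path
    def run_len(r):
        i, j = r
        return 0.0 if j == i else path_length(pts[i:j + 1], params)
    i, j = max(runs, key=run_len)
    water = pts[i:j + 1]

    # north-coast crossing: interpolate back from the first over-water fix
    (dlat, dlon), _ = first_boundary_crossing(
        (pts[i - 1].lat, pts[i - 1].lon), (water[0].lat, water[0].lon),
        coastlines.north.boundary)
    d_out = gc_distance((dlat, dlon), (water[0].lat, water[0].lon), params)
    t_depart = water[0].timestamp - timedelta(
        seconds=d_out * 1000.0 / params.mean_flight_speed)
    # south-coast crossing: interpolate forward from the last over-water fix
    (alat, alon), _ = first_boundary_crossing(
        (pts[j + 1].lat, pts[j + 1].lon), (water[-1].lat, water[-1].lon),
        coastlines.south.boundary)
    d_in = gc_distance((water[-1].lat, water[-1].lon), (alat, alon), params)
    t_arrive = water[-1].timestamp + timedelta(
        seconds=d_in * 1000.0 / params.mean_flight_speed)

    length = d_out + d_in
    if len(water) == 1:
        logger.warning("bird %s: single over-water fix; flight length is a "
                       "lower bound", track.bird_id)
    else:
        length += path_length(water, params)
    duration_days = (t_arrive - t_depart).total_seconds() / 86400.0
    implied_floor = length / (MAX_PLAUSIBLE_SPEED_MS * 86.4)  # km / (km/day)
    speed_ok = duration_days >= implied_floor
    if not speed_ok:
        logger.warning("bird %s: crossing implies > %.0f m/s sustained speed",
                       track.bird_id, MAX_PLAUSIBLE_SPEED_MS)

    vecs = ll_to_vec([p.lat for p in water], [p.lon for p in water])
    phase = Phase("transoceanic", t_depart, t_arrive, _centroid(vecs),
                  list(range(i, j + 1)))
    metrics = {
        "departure_time": t_depart,
        "arrival_time": t_arrive,
        "duration_days": duration_days,
        "length_km": length,
        "departure_lat": float(dlat),
        "speed_ok": bool(speed_ok),
    }
    return phase, metrics


def summarize_journey(track: BirdTrack, departure: datetime, arrival: datetime,
                      ocean: dict | None = None, grounded: bool = False,
                      params: GeoParams = DEFAULT_PARAMS) -> JourneySummary:
    """Assemble the per-journey record feeding the statistics layer."""
    mig = [p for p in track.points if departure <= p.timestamp <= arrival]
    if len(mig) < 2:
        raise SegmentationError("fewer than 2 fixes between departure and arrival")
    total = path_length(mig, params)
    duration = (arrival - departure).total_seconds() / 86400.0
    if duration <= 0:
        raise SegmentationError("non-positive migration duration")
    return JourneySummary(
        bird_id=track.bird_id,
        population=track.population,
        year=departure.year,
        departure_date=departure,
        arrival_date=arrival,
        total_distance=total,
        duration=duration,
        rate_of_advance=total / duration,
        ocean_departure_lat=None if ocean is None else ocean["departure_lat"],
        ocean_flight_length=None if ocean is None else ocean["length_km"],
        ocean_flight_duration=None if ocean is None else ocean["duration_days"],
        grounded=grounded,
    )
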