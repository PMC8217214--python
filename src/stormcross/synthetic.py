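"""Synthetic telemetry and storm basins with exact ground truth.

The generator emulates the statistical structure the analysis assumes, not
the real geography: two shorebird populations that cross a toy Atlantic
between rectangular continents, and a basin of six-hourly cyclone tracks
drifting west with occasional recurvature.  Every generated quantity
(departure instants, coast-crossing latitudes, over-water path lengths and
durations, planted bird-storm separations) is recorded as ground truth so
each pipeline stage can be scored against what was actually simulated.

Route archetypes are parameterised by the field cohort values: the northern
("MackenzieDelta") population departs near 47.5 deg N on long crossings
(mean 5440 km over 6.1 days) far out to sea; the southern ("HudsonBay")
population departs near 37.0 deg N on shorter crossings (mean 3643 km over
4.5 days) through an island arc.  Per-journey standard deviations are the
printed standard errors scaled by sqrt(n) of the respective cohorts.

Everything is deterministic under a fixed seed: independent child generators
are derived per component, and all serialisation is fixed-precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, box

from .formats_io import (BirdTrack, StormPoint, StormTrack, TrackPoint)
from .geodesy import (DEFAULT_PARAMS, destination_point, gc_distance,
                      initial_bearing, slerp)
from .migration import Coastlines

logger = logging.getLogger(__name__)

MAX_FLIGHT_SPEED_MS = 30.0
MAX_STORM_SPEED_KT = 40.0

# ARGOS location-class sampling: class frequencies and 1-sigma noise (km),
# using each class's published error bound as the 1-sigma scale
LC_CLASSES = np.array(["3", "2", "1", "0", "A", "B"])
LC_PROBS = np.array([0.25, 0.30, 0.30, 0.08, 0.05, 0.02])
LC_SIGMA_KM = {"3": 0.15, "2": 0.35, "1": 1.0, "0": 2.0, "A": 5.0, "B": 10.0}

STORM_NAMES = [
    "ALMA", "BERYL", "CHRIS", "DEBBY", "ERNESTO", "FLORENCE", "GORDON",
    "HELENE", "ISAAC", "JOYCE", "KIRK", "LESLIE", "MICHAEL", "NADINE",
    "OSCAR", "PATTY", "RAFAEL", "SARA", "TONY", "VALERIE", "WILLIAM",
]


@dataclass(frozen=True)
class PopulationArchetype:
    name: str
    n_birds: int
    breeding: tuple[float, float]          # (lat, lon)
    breeding_departure_doy: float          # mean day-of-year
    breeding_departure_sd: float           # days
    staging_coast_lon: float               # lon of the staging site (on-coast)
    departure_lat_mean: float
    departure_lat_sd: float
    ocean_length_mean: float               # km
    ocean_length_sd: float
    ocean_duration_mean: float             # days
    ocean_duration_sd: float
    arrival_lon: float                     # where the crossing makes landfall
    duty_cycle: tuple[float, float] = (48.0, 10.0)  # hours off / on


# cohort SEs scaled to per-journey SDs: sd = se * sqrt(n)
MACKENZIE_DELTA = PopulationArchetype(
    name="MackenzieDelta", n_birds=13, breeding=(69.0, -134.0),
    breeding_departure_doy=188.0, breeding_departure_sd=8.0,  # ~7 Jul
    staging_coast_lon=-59.05,
    departure_lat_mean=47.5, departure_lat_sd=0.44 * np.sqrt(13),
    ocean_length_mean=5440.0, ocean_length_sd=120.3 * np.sqrt(13),
    ocean_duration_mean=6.1, ocean_duration_sd=0.18 * np.sqrt(13),
    arrival_lon=-55.0)

HUDSON_BAY = PopulationArchetype(
    name="HudsonBay", n_birds=11, breeding=(58.0, -94.0),
    breeding_departure_doy=206.0, breeding_departure_sd=10.0,  # ~25 Jul
    staging_coast_lon=-74.85,
    departure_lat_mean=37.0, departure_lat_sd=0.65 * np.sqrt(11),
    ocean_length_mean=3643.0, ocean_length_sd=196.2 * np.sqrt(11),
    ocean_duration_mean=4.5, ocean_duration_sd=0.29 * np.sqrt(11),
    arrival_lon=-58.0)


@dataclass(frozen=True)
class StormFieldConfig:
    n_storms: int = 30
    year_min: int = 2008
    year_max: int = 2019
    genesis_lat: tuple[float, float] = (10.0, 16.0)
    genesis_lon: tuple[float, float] = (-65.0, -52.0)
    westward_drift_ms: float = 6.0         # mean westward speed
    drift_sd_ms: float = 1.2
    recurvature_prob: float = 0.4
    genesis_wind_kt: tuple[float, float] = (25.0, 35.0)
    intensification_kt: float = 2.5        # mean 6-hourly wind increment
    intensification_sd_kt: float = 3.0
    duration_days: tuple[float, float] = (5.0, 12.0)
    season_start: tuple[int, int] = (7, 15)
    season_end: tuple[int, int] = (11, 30)


@dataclass(frozen=True)
class PlantSpec:
    """One requested bird x storm near-miss."""

    bird_id: str
    year: int
    storm_id: str
    time: datetime
    separation_km: float
    grounded: bool = False   # plant over a stationary phase centroid


@dataclass
class BirdTruth:
    bird_id: str
    population: str
    year: int
    breeding_departure: datetime
    winter_arrival: datetime
    ocean_departure: datetime
    ocean_arrival: datetime
    ocean_departure_lat: float
    ocean_length_km: float
    ocean_duration_days: float
    anchors: list[tuple[datetime, float, float]]  # the true piecewise path


@dataclass
class PlantTruth:
    spec: PlantSpec
    achieved_separation_km: float
    bird_position: tuple[float, float]


@dataclass
class GroundTruth:
    birds: dict = field(default_factory=dict)    # (bird_id, year) -> BirdTruth
    storms: dict = field(default_factory=dict)   # storm_id -> list of records
    plants: list = field(default_factory=list)   # PlantTruth


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    populations: tuple[PopulationArchetype, ...] = (MACKENZIE_DELTA, HUDSON_BAY)
    journeys_per_bird: int = 2
    storm_field: StormFieldConfig = StormFieldConfig()
    fix_interval_h: float = 2.0            # cadence inside an on-window
    # automatic planting: fraction of each population's journeys given an
    # in-flight near-miss (ordering mirrors the two routes' risk contrast)
    plant_fraction: dict | None = None
    plant_separation_km: tuple[float, float] = (30.0, 120.0)

    def fractions(self) -> dict:
        return self.plant_fraction or {"MackenzieDelta": 0.12, "HudsonBay": 0.6}


# ---------------------------------------------------------------------------
# toy geography


def default_coastlines() -> Coastlines:
    """Rectangular continents bracketing a toy Atlantic."""
    north = MultiPolygon([
        box(-140.0, 44.0, -59.0, 80.0),    # northern block (boreal coast)
        box(-140.0, 24.0, -74.8, 44.0),    # southern block (south Atlantic coast)
    ])
    south = MultiPolygon([box(-82.0, -25.0, -40.0, 6.5)])
    return Coastlines(north=north, south=south, islands=default_islands())


def default_islands() -> MultiPolygon:
    """A five-island toy Antilles arc on the southern route."""
    centers = [(18.4, -66.1), (18.0, -63.1), (16.3, -61.5),
               (14.7, -61.0), (13.2, -59.5)]
    half = 0.45
    return MultiPolygon([box(lon - half, lat - half, lon + half, lat + half)
                         for lat, lon in centers])


# ---------------------------------------------------------------------------
# bird tracks


def _offset_waypoint(p0, p1, target_km, params=DEFAULT_PARAMS):
    """Mid-route waypoint displaced perpendicular to the direct great circle
    so the two-leg path has the requested length (bisection on the offset)."""
    direct = gc_distance(p0, p1, params)
    if target_km <= direct * 1.0005:
        return None  # direct route is already the right length
    mid = slerp(p0, p1, 0.5)
    mid = (float(mid[0]), float(mid[1]))
    brg = (initial_bearing(p0, p1) + 270.0) % 360.0  # left of travel = seaward east

    def two_leg(off):
        m = destination_point(mid, brg, off, params)
        return gc_distance(p0, m, params) + gc_distance(m, p1, params)

    lo, hi = 0.0, 0.55 * target_km
    if two_leg(hi) < target_km:
        raise ValueError("requested ocean length unreachable")
    for _ in range(60):
        cm = 0.5 * (lo + hi)
        if two_leg(cm) < target_km:
            lo = cm
        else:
            hi = cm
    return destination_point(mid, brg, 0.5 * (lo + hi), params)


def _anchor_path(anchors, t):
    """Position on the piecewise constant-pace great-circle path at time t."""
    for (t0, la0, lo0), (t1, la1, lo1) in zip(anchors[:-1], anchors[1:]):
        if t0 <= t <= t1:
            span = (t1 - t0).total_seconds()
            frac = 0.0 if span == 0 else (t - t0).total_seconds() / span
            lat, lon = slerp((la0, lo0), (la1, lo1), frac)
            return float(lat), float(lon)
    if t < anchors[0][0]:
        return anchors[0][1], anchors[0][2]
    return anchors[-1][1], anchors[-1][2]


def _journey_anchors(arch: PopulationArchetype, year: int,
                     rng: np.random.Generator) -> BirdTruth:
    day0 = datetime(year, 1, 1)
    dep_breed = day0 + timedelta(days=float(
        rng.normal(arch.breeding_departure_doy, arch.breeding_departure_sd)))
    dep_breed = dep_breed.replace(microsecond=0)
    breed_start = dep_breed - timedelta(days=30)

    lat_dep = float(rng.normal(arch.departure_lat_mean, arch.departure_lat_sd))
    staging = (lat_dep, arch.staging_coast_lon)
    d_transit = gc_distance(arch.breeding, staging)
    transit_days = max(2.0, d_transit / (12.0 * 86.4))  # ~12 m/s continental pace
    arr_staging = dep_breed + timedelta(days=transit_days)
    stage_days = float(np.clip(rng.normal(12.0, 4.0), 5.0, 25.0))
    dep_ocean = arr_staging + timedelta(days=stage_days)

    # redraw until the implied crossing speed is plausible
    for _ in range(100):
        length = float(rng.normal(arch.ocean_length_mean, arch.ocean_length_sd))
        dur = float(rng.normal(arch.ocean_duration_mean, arch.ocean_duration_sd))
        if dur <= 0.5 or length <= 500.0:
            continue
        speed = length * 1000.0 / (dur * 86400.0)
        if 5.0 <= speed <= MAX_FLIGHT_SPEED_MS:
            break
        logger.debug("redraw: implied crossing speed %.1f m/s", speed)
    arrival = (6.5, arch.arrival_lon)
    way = _offset_waypoint(staging, arrival, length)
    arr_ocean = dep_ocean + timedelta(days=dur)

    inland = (6.0, arch.arrival_lon - 0.3)
    winter = (3.0, -55.5)
    arr_inland = arr_ocean + timedelta(days=0.3)
    arr_winter = arr_inland + timedelta(days=3.0)
    winter_end = arr_winter + timedelta(days=40)

    anchors = [
        (breed_start,) + arch.breeding,
        (dep_breed,) + arch.breeding,
        (arr_staging,) + staging,
        (dep_ocean,) + staging,
    ]
    if way is not None:
        t_way = dep_ocean + timedelta(
            days=dur * gc_distance(staging, way) / length)
        anchors.append((t_way,) + way)
    anchors += [
        (arr_ocean,) + arrival,
        (arr_inland,) + inland,
        (arr_winter,) + winter,
        (winter_end,) + winter,
    ]
    return BirdTruth(
        bird_id="", population=arch.name, year=year,
        breeding_departure=dep_breed, winter_arrival=arr_winter,
        ocean_departure=dep_ocean, ocean_arrival=arr_ocean,
        ocean_departure_lat=lat_dep, ocean_length_km=length,
        ocean_duration_days=dur, anchors=anchors)


def _sample_fixes(truth: BirdTruth, bird_id: str, duty: tuple[float, float],
                  fix_interval_h: float, rng: np.random.Generator
                  ) -> list[TrackPoint]:
    t0 = truth.anchors[0][0]
    t1 = truth.anchors[-1][0]
    off_h, on_h = duty
    cycle = timedelta(hours=off_h + on_h)
    points = []
    t_cycle = t0
    while t_cycle < t1:
        t = t_cycle
        on_end = min(t_cycle + timedelta(hours=on_h), t1)
        while t <= on_end:
            lat, lon = _anchor_path(truth.anchors, t)
            lc = str(rng.choice(LC_CLASSES, p=LC_PROBS))
            sig = LC_SIGMA_KM[lc]
            dlat = rng.normal(0.0, sig) / 111.32
            dlon = rng.normal(0.0, sig) / (111.32 * max(0.2, np.cos(np.deg2rad(lat))))
            points.append(TrackPoint(
                bird_id, t.replace(microsecond=0),
                float(np.clip(lat + dlat, -89.9, 89.9)),
                float(((lon + dlon) + 180.0) % 360.0 - 180.0), lc))
            t += timedelta(hours=fix_interval_h)
        t_cycle += cycle
    return points


def generate_bird_tracks(config: ScenarioConfig
                         ) -> tuple[list[BirdTrack], GroundTruth]:
    """One BirdTrack per journey (bird x year), plus exact ground truth."""
    truth = GroundTruth()
    tracks: list[BirdTrack] = []
    years = list(range(config.storm_field.year_min, config.storm_field.year_max + 1))
    for p_i, arch in enumerate(config.populations):
        prefix = "MD" if arch.name == "MackenzieDelta" else (
            "HB" if arch.name == "HudsonBay" else arch.name[:2].upper())
        for b in range(arch.n_birds):
            bird_id = f"{prefix}{b + 1:02d}"
            rng = np.random.default_rng([config.seed, 101, p_i, b])
            year0 = int(rng.integers(years[0], years[-1] - config.journeys_per_bird + 2))
            for j in range(config.journeys_per_bird):
                year = year0 + j
                jt = _journey_anchors(arch, year, rng)
                jt.bird_id = bird_id
                pts = _sample_fixes(jt, bird_id, arch.duty_cycle,
                                    config.fix_interval_h, rng)
                tracks.append(BirdTrack(bird_id, pts, population=arch.name,
                                        duty_cycle=arch.duty_cycle))
                truth.birds[(bird_id, year)] = jt
    return tracks, truth


# ---------------------------------------------------------------------------
# storm basin


def _season_bounds(year: int, cfg: StormFieldConfig):
    return (datetime(year, *cfg.season_start), datetime(year, *cfg.season_end))


def generate_storm_basin(config: ScenarioConfig
                         ) -> tuple[list[StormTrack], GroundTruth]:
    """Six-hourly cyclone tracks: westward drift, Bernoulli recurvature,
    bounded random-walk winds spanning TD through hurricane strength."""
    cfg = config.storm_field
    truth = GroundTruth()
    storms: list[StormTrack] = []
    years = list(range(cfg.year_min, cfg.year_max + 1))
    per_year: dict[int, int] = {}
    for s in range(cfg.n_storms):
        rng = np.random.default_rng([config.seed, 202, s])
        year = int(rng.choice(years))
        per_year[year] = per_year.get(year, 0) + 1
        num = per_year[year]
        storm_id = f"AL{num:02d}{year}"
        name = STORM_NAMES[s % len(STORM_NAMES)]
        dur_days = float(rng.uniform(*cfg.duration_days))
        t_lo, t_hi = _season_bounds(year, cfg)
        span_days = (t_hi - t_lo).days - dur_days
        genesis_t = t_lo + timedelta(days=float(rng.uniform(0, max(1.0, span_days))))
        genesis_t = genesis_t.replace(hour=int(rng.choice([0, 6, 12, 18])),
                                      minute=0, second=0, microsecond=0)
        lat = float(rng.uniform(*cfg.genesis_lat))
        lon = float(rng.uniform(*cfg.genesis_lon))
        wind = float(rng.uniform(*cfg.genesis_wind_kt))
        recurves = bool(rng.random() < cfg.recurvature_prob)
        t_recurve = float(rng.uniform(0.4, 0.8)) * dur_days if recurves else np.inf

        n_steps = int(dur_days * 4)
        pts = []
        for k in range(n_steps):
            t = genesis_t + timedelta(hours=6 * k)
            age_days = 6 * k / 24.0
            status = "TD" if wind < 34 else ("TS" if wind < 64 else "HU")
            if lat > 45.0:
                status = "EX"
            pts.append(StormPoint(storm_id, name, t, round(lat, 1),
                                  round(lon, 1), int(round(wind)), status))
            # 6-hour kinematics (degrees)
            u_ms = -cfg.westward_drift_ms + float(rng.normal(0, cfg.drift_sd_ms))
            v_ms = 0.8 + float(rng.normal(0, 0.6))
            if age_days > t_recurve:
                u_ms += 6.0
                v_ms += 4.0
            lon += u_ms * 21600.0 / (111320.0 * max(0.3, np.cos(np.deg2rad(lat))))
            lat += v_ms * 21600.0 / 111320.0
            # wind random walk: build, then decay late / after recurvature
            building = age_days < 0.6 * dur_days and age_days < t_recurve
            drift = cfg.intensification_kt if building else -cfg.intensification_kt
            wind = float(np.clip(wind + rng.normal(drift, cfg.intensification_sd_kt),
                                 15.0, 140.0))
        storms.append(StormTrack(storm_id, name, pts))
        truth.storms[storm_id] = [(p.timestamp, p.lat, p.lon, p.max_wind)
                                  for p in pts]
    storms.sort(key=lambda s: (s.points[0].timestamp, s.storm_id))
    return storms, truth


# ---------------------------------------------------------------------------
# planted encounters


def _storm_interp(points, t: datetime):
    ts = np.array([(p.timestamp - points[0].timestamp).total_seconds()
                   for p in points])
    q = (t - points[0].timestamp).total_seconds()
    lat = float(np.interp(q, ts, [p.lat for p in points]))
    lon = float(np.interp(q, ts, [p.lon for p in points]))
    return lat, lon


def _track_position(track: BirdTrack, t: datetime) -> tuple[float, float]:
    """Great-circle interpolation of the observed fixes at instant t."""
    pts = track.points
    ts = [p.timestamp for p in pts]
    if not ts[0] <= t <= ts[-1]:
        raise ValueError("instant outside the track span")
    k = max(0, min(len(pts) - 2,
                   int(np.searchsorted(np.array(ts, dtype="datetime64[us]"),
                                       np.datetime64(t, "us"), "right")) - 1))
    a, b = pts[k], pts[k + 1]
    span = (b.timestamp - a.timestamp).total_seconds()
    frac = 0.0 if span == 0 else (t - a.timestamp).total_seconds() / span
    lat, lon = slerp((a.lat, a.lon), (b.lat, b.lon), frac)
    return float(lat), float(lon)


def plant_encounters(tracks: list[BirdTrack], storms: list[StormTrack],
                     plants: list[PlantSpec], truth: GroundTruth,
                     warp_window_h: float = 36.0) -> list[StormTrack]:
    """Locally warp storm tracks so each plant's storm centre passes at the
    requested separation from the bird's interpolated position at the
    requested instant.

    The bird position is interpolated from the analysis-grade track (ARGOS
    classes 1-3), matching how the detection stage will see the bird; duty
    cycle gaps mean this can differ from the simulated true path.  The
    positional offset is tapered linearly to zero over +/- warp_window_h
    around the plant time, preserving the basin's large-scale statistics.
    Plant truth (achieved separation after warping) is appended to
    ``truth.plants``.
    """
    from .formats_io import filter_by_location_class

    out = {s.storm_id: s for s in storms}
    journeys: dict[tuple[str, int], BirdTrack] = {}
    for t in tracks:
        if not t.is_empty:
            journeys[(t.bird_id, t.points[0].timestamp.year)] = t
    for spec in plants:
        storm = out.get(spec.storm_id)
        if storm is None:
            raise ValueError(f"unknown storm {spec.storm_id}")
        track = journeys.get((spec.bird_id, spec.year))
        if track is None:
            raise ValueError(f"no journey track for {spec.bird_id}/{spec.year}")
        if not (storm.points[0].timestamp <= spec.time <= storm.points[-1].timestamp):
            raise ValueError(f"plant time outside storm {spec.storm_id} span")
        analysis = filter_by_location_class(track)
        blat, blon = _track_position(analysis, spec.time)
        slat, slon = _storm_interp(storm.points, spec.time)
        # put the storm centre at the requested separation, approaching from
        # the east (the storm's direction of travel is westward)
        tgt_lat, tgt_lon = destination_point((blat, blon), 90.0,
                                             spec.separation_km)
        dlat, dlon = tgt_lat - slat, tgt_lon - slon
        new_pts = []
        for p in storm.points:
            w = max(0.0, 1.0 - abs((p.timestamp - spec.time).total_seconds())
                    / (warp_window_h * 3600.0))
            # full precision here: the 0.1-degree rounding belongs to HURDAT2
            # serialisation, not to the planted geometry
            new_pts.append(StormPoint(
                p.storm_id, p.name, p.timestamp,
                float(np.clip(p.lat + w * dlat, -89.9, 89.9)),
                float(p.lon + w * dlon),
                p.max_wind, p.status, p.record_id))
        # implied 6-hour displacement must stay physically plausible
        for a, b in zip(new_pts[:-1], new_pts[1:]):
            step_km = gc_distance((a.lat, a.lon), (b.lat, b.lon))
            if step_km > MAX_STORM_SPEED_KT * 1.852 * 6.0 * 2.5:
                raise ValueError(
                    f"plant for {spec.bird_id} x {spec.storm_id} needs an "
                    "implausibly fast storm; choose a nearer storm or time")
        warped = StormTrack(storm.storm_id, storm.name, new_pts)
        out[storm.storm_id] = warped
        # recomputed separation at the plant instant (post-hoc check)
        achieved = gc_distance(_track_position(analysis, spec.time),
                               _storm_interp(new_pts, spec.time))
        truth.plants.append(PlantTruth(spec, float(achieved), (blat, blon)))
    return [out[s.storm_id] for s in storms]


def shift_storm(storm: StormTrack, hours: int) -> StormTrack:
    """Translate a whole storm track in time (multiples of 6 h keep the
    synoptic alignment)."""
    dt = timedelta(hours=hours)
    pts = [StormPoint(p.storm_id, p.name, p.timestamp + dt, p.lat, p.lon,
                      p.max_wind, p.status, p.record_id)
           for p in storm.points]
    return StormTrack(storm.storm_id, storm.name, pts)


def make_default_plants(config: ScenarioConfig, tracks_truth: GroundTruth,
                        storms: list[StormTrack]
                        ) -> tuple[list[PlantSpec], list[StormTrack]]:
    """Choose journeys to receive an in-flight near-miss, at the per-population
    fractions that mirror the two routes' designed risk contrast.

    Each planted journey is paired with an unused same-year storm; the storm
    is re-timed (whole-track 6-hourly shift) so it is active at mid-crossing,
    and the plant instant is snapped to the storm's synoptic grid so the
    positional warp is exact there.  Returns the plant list and the (possibly
    re-timed) storm list.
    """
    rng = np.random.default_rng([config.seed, 303])
    fractions = config.fractions()
    by_id = {s.storm_id: s for s in storms}
    used_storms: set[str] = set()
    plants: list[PlantSpec] = []
    for (bird_id, year), bt in sorted(tracks_truth.birds.items()):
        frac = fractions.get(bt.population, 0.0)
        if rng.random() >= frac:
            continue
        t_mid = bt.ocean_departure + (bt.ocean_arrival - bt.ocean_departure) / 2
        candidates = [s for s in by_id.values()
                      if s.storm_id not in used_storms
                      and s.points[0].timestamp.year == year]
        if not candidates:
            logger.info("no free storm in %d for %s; journey unplanted",
                        year, bird_id)
            continue
        storm = candidates[int(rng.integers(len(candidates)))]
        used_storms.add(storm.storm_id)
        mid_storm = storm.points[len(storm.points) // 2].timestamp
        shift_h = 6 * round((t_mid - mid_storm).total_seconds() / 21600.0)
        if shift_h:
            storm = shift_storm(storm, shift_h)
            by_id[storm.storm_id] = storm
        # snap the plant instant to the storm's synoptic grid
        t_plant = min((p.timestamp for p in storm.points),
                      key=lambda t: abs((t - t_mid).total_seconds()))
        if not (bt.ocean_departure <= t_plant <= bt.ocean_arrival):
            logger.info("snapped plant time misses the crossing for %s/%d",
                        bird_id, year)
            continue
        sep = float(rng.uniform(*config.plant_separation_km))
        plants.append(PlantSpec(bird_id, year, storm.storm_id, t_plant, sep))
    return plants, [by_id[s.storm_id] for s in storms]


def generate_scenario(config: ScenarioConfig):
    """Full default scenario: tracks, planted storm basin, geography, truth."""
    tracks, truth = generate_bird_tracks(config)
    storms, _storm_truth = generate_storm_basin(config)
    plants, storms = make_default_plants(config, truth, storms)
    storms = plant_encounters(tracks, storms, plants, truth)
    truth.storms = {s.storm_id: [(p.timestamp, p.lat, p.lon, p.max_wind)
                                 for p in s.points] for s in storms}
    return tracks, storms, default_coastlines(), truth
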