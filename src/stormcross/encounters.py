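"""Bird x storm encounter detection, intensity and response classification.

An in-flight encounter is declared when the bird and a storm centre, both
interpolated onto a shared time grid, come within an encounter radius of each
other; one encounter is recorded per maximal below-radius interval, at the
instant of minimum separation.  The source best tracks record position every
six hours and bird fixes arrive on multi-hour duty cycles, so the default
grid step is 30 minutes — finer steps add nothing.

Storm intensity at the encounter instant is classified on the Saffir-Simpson
wind scale using the published mile-per-hour band edges; best-track winds are
knots and are converted at 1.15078 mph/kt.

The behavioural response is classified as grounding (a stationary interval on
an island beginning shortly after the encounter), detour (migration bearing
deflected by more than a threshold angle, default 20 deg, between the day
before and the day after), or none; grounding supersedes detour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

import pandas as pd

from .formats_io import BirdTrack, StormTrack, MISSING_WIND
from .geodesy import DEFAULT_PARAMS, GeoParams, initial_bearing, ll_to_vec, vec_to_ll
from .migration import JourneySummary, Phase, detect_residency

logger = logging.getLogger(__name__)

KT_TO_MPH = 1.15078

SAFFIR_SIMPSON_BANDS = (
    ("TD", 0.0, 39.0),     # <= 38 mph
    ("TS", 39.0, 74.0),    # 39-73
    ("C1", 74.0, 96.0),    # 74-95
    ("C2", 96.0, 111.0),   # 96-110
    ("C3", 111.0, 130.0),  # 111-129
    ("C4", 130.0, 157.0),  # 130-156
    ("C5", 157.0, float("inf")),
)


@dataclass(frozen=True)
class EncounterConfig:
    encounter_radius_km: float = 300.0
    grounded_radius_km: float = 100.0
    sync_step_min: float = 30.0
    detour_angle_deg: float = 20.0
    detour_pre_window_h: float = 24.0
    detour_post_window_h: float = 48.0
    low_confidence_gap_h: float = 72.0

    def __post_init__(self) -> None:
        for name in ("encounter_radius_km", "grounded_radius_km",
                     "sync_step_min", "detour_angle_deg",
                     "detour_pre_window_h", "detour_post_window_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Encounter:
    bird_id: str
    storm_id: str
    storm_name: str
    time: datetime
    lat: float
    lon: float
    bird_state: str              # 'in_flight' | 'grounded'
    storm_category: str          # TD | TS | C1..C5
    min_separation_km: float
    response: str = "unclassified"
    low_confidence: bool = False


def saffir_simpson_category(wind_mph: float) -> str:
    """Saffir-Simpson label from sustained wind in mph.

    Bands (inclusive integer mph): TD <= 38, TS 39-73, C1 74-95, C2 96-110,
    C3 111-129, C4 130-156, C5 >= 157.
    """
    if wind_mph < 0:
        raise ValueError("wind speed must be non-negative")
    for label, lo, hi in SAFFIR_SIMPSON_BANDS:
        if lo <= wind_mph < hi:
            return label
    return "C5"


# ---------------------------------------------------------------------------
# interpolation helpers (vectorised over a shared time grid)

_EPOCH = datetime(1970, 1, 1)


def _to_sec(ts: datetime) -> float:
    return (ts - _EPOCH).total_seconds()


def _track_arrays(points):
    t = np.array([_to_sec(p.timestamp) for p in points])
    lat = np.array([p.lat for p in points])
    lon = np.array([p.lon for p in points])
    return t, lat, lon


def _interp_positions(t, lat, lon, query):
    """Great-circle (slerp) interpolation of a fix series at query seconds."""
    idx = np.clip(np.searchsorted(t, query, side="right") - 1, 0, len(t) - 2)
    t0, t1 = t[idx], t[idx + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(t1 > t0, (query - t0) / (t1 - t0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    v0 = ll_to_vec(lat[idx], lon[idx])
    v1 = ll_to_vec(lat[idx + 1], lon[idx + 1])
    dot = np.clip(np.sum(v0 * v1, axis=-1), -1.0, 1.0)
    om = np.arccos(dot)
    so = np.sin(om)
    small = so < 1e-12
    so_safe = np.where(small, 1.0, so)
    a = np.where(small, 1.0 - frac, np.sin((1.0 - frac) * om) / so_safe)
    b = np.where(small, frac, np.sin(frac * om) / so_safe)
    v = a[:, None] * v0 + b[:, None] * v1
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    return vec_to_ll(v)


def _vec_distance_km(lat1, lon1, lat2, lon2,
                     params: GeoParams = DEFAULT_PARAMS):
    v1 = ll_to_vec(lat1, lon1)
    v2 = ll_to_vec(lat2, lon2)
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    return np.arctan2(cross, dot) * params.earth_radius_km


def _storm_wind_at(storm: StormTrack, t_sec: float) -> float:
    """Linearly interpolated wind (knots) at an instant; missing -> nan."""
    recs = [(_to_sec(p.timestamp), p.max_wind) for p in storm.points
            if p.max_wind != MISSING_WIND]
    if not recs:
        return float("nan")
    ts = np.array([r[0] for r in recs])
    ws = np.array([r[1] for r in recs], dtype=float)
    return float(np.interp(t_sec, ts, ws))


# ---------------------------------------------------------------------------

def detect_inflight_encounters(track: BirdTrack, storms: list[StormTrack],
                               config: EncounterConfig = EncounterConfig(),
                               params: GeoParams = DEFAULT_PARAMS
                               ) -> list[Encounter]:
    """Spatiotemporal intersections of a flying bird with storm centres."""
    if len(track.points) < 2:
        return []
    bt, blat, blon = _track_arrays(track.points)
    step = config.sync_step_min * 60.0
    out: list[Encounter] = []
    for storm in storms:
        if len(storm.points) < 2:
            continue
        st, slat, slon = _track_arrays(storm.points)
        lo = max(bt[0], st[0])
        hi = min(bt[-1], st[-1])
        if hi <= lo:
            continue
        grid = np.arange(lo, hi + step, step)
        grid = grid[grid <= hi]
        if grid.size == 0:
            continue
        glat, glon = _interp_positions(bt, blat, blon, grid)
        hlat, hlon = _interp_positions(st, slat, slon, grid)
        sep = _vec_distance_km(glat, glon, hlat, hlon, params)
        close = sep <= config.encounter_radius_km
        if not close.any():
            continue
        # maximal runs of below-radius separation
        edges = np.flatnonzero(np.diff(close.astype(int)))
        starts = [0] if close[0] else []
        starts += [e + 1 for e in edges if close[e + 1]]
        ends = [e for e in edges if close[e]]
        ends += [len(close) - 1] if close[-1] else []
        for a, b in zip(starts, ends):
            k = a + int(np.argmin(sep[a:b + 1]))
            t_enc = _EPOCH + timedelta(seconds=float(grid[k]))
            wind_kt = _storm_wind_at(storm, float(grid[k]))
            category = ("TD" if np.isnan(wind_kt)
                        else saffir_simpson_category(wind_kt * KT_TO_MPH))
            if np.isnan(wind_kt):
                logger.warning("storm %s: no wind at encounter; category "
                               "defaulted to TD", storm.storm_id)
            fix_idx = int(np.clip(np.searchsorted(bt, grid[k]) - 1, 0, len(bt) - 2))
            gap_h = (bt[fix_idx + 1] - bt[fix_idx]) / 3600.0
            out.append(Encounter(
                bird_id=track.bird_id, storm_id=storm.storm_id,
                storm_name=storm.name, time=t_enc,
                lat=float(glat[k]), lon=float(glon[k]),
                bird_state="in_flight", storm_category=category,
                min_separation_km=float(sep[k]),
                low_confidence=gap_h > config.low_confidence_gap_h))
    out.sort(key=lambda e: e.time)
    return out


def detect_grounded_encounters(phase: Phase, bird_id: str,
                               storms: list[StormTrack],
                               config: EncounterConfig = EncounterConfig(),
                               params: GeoParams = DEFAULT_PARAMS
                               ) -> list[Encounter]:
    """Storm centres passing over a grounded bird's position.

    One encounter per storm whose interpolated centre comes within the
    grounded radius of the stationary phase's centroid during the phase.
    """
    clat, clon = phase.centroid
    step = config.sync_step_min * 60.0
    out: list[Encounter] = []
    for storm in storms:
        if len(storm.points) < 2:
            continue
        st, slat, slon = _track_arrays(storm.points)
        lo = max(_to_sec(phase.start), st[0])
        hi = min(_to_sec(phase.end), st[-1])
        if hi <= lo:
            continue
        grid = np.arange(lo, hi + step, step)
        grid = grid[grid <= hi]
        hlat, hlon = _interp_positions(st, slat, slon, grid)
        sep = _vec_distance_km(np.full_like(grid, clat), np.full_like(grid, clon),
                               hlat, hlon, params)
        k = int(np.argmin(sep))
        if sep[k] <= config.grounded_radius_km:
            t_enc = _EPOCH + timedelta(seconds=float(grid[k]))
            wind_kt = _storm_wind_at(storm, float(grid[k]))
            category = ("TD" if np.isnan(wind_kt)
                        else saffir_simpson_category(wind_kt * KT_TO_MPH))
            out.append(Encounter(
                bird_id=bird_id, storm_id=storm.storm_id,
                storm_name=storm.name, time=t_enc, lat=clat, lon=clon,
                bird_state="grounded", storm_category=category,
                min_separation_km=float(sep[k]), response="grounded"))
    out.sort(key=lambda e: e.time)
    return out


def _position_at(track: BirdTrack, t: datetime):
    bt, blat, blon = _track_arrays(track.points)
    ts = _to_sec(t)
    if ts < bt[0] or ts > bt[-1]:
        return None
    lat, lon = _interp_positions(bt, blat, blon, np.array([ts]))
    return float(lat[0]), float(lon[0])


def classify_response(track: BirdTrack, encounter: Encounter,
                      islands: BaseGeometry | None,
                      config: EncounterConfig = EncounterConfig()) -> str:
    """none / detour / grounded / indeterminate for one in-flight encounter.

    Grounded: a stationary interval (>= 1 day within 25 km) starting within
    the post-encounter window whose centroid lies on an island polygon.
    Detour: bearing of the post-window displacement differs from the
    pre-window bearing by more than the detour angle (circular difference).
    Grounding supersedes detour.
    """
    t = encounter.time
    post_end = t + timedelta(hours=config.detour_post_window_h)
    if islands is not None:
        sub_pts = [p for p in track.points
                   if t <= p.timestamp <= post_end + timedelta(days=10)]
        if len(sub_pts) >= 2:
            sub = BirdTrack(track.bird_id, sub_pts)
            for ph in detect_residency(sub, radius_km=25.0, min_days=1.0):
                if ph.start <= post_end and islands.contains(
                        Point(ph.centroid[1], ph.centroid[0])):
                    return "grounded"

    pre_a = _position_at(track, t - timedelta(hours=config.detour_pre_window_h))
    pre_b = _position_at(track, t)
    post_b = _position_at(track, t + timedelta(hours=config.detour_pre_window_h))
    if pre_a is None or pre_b is None or post_b is None:
        return "indeterminate"
    try:
        b_pre = initial_bearing(pre_a, pre_b)
        b_post = initial_bearing(pre_b, post_b)
    except ValueError:
        return "indeterminate"
    diff = abs((b_post - b_pre + 180.0) % 360.0 - 180.0)
    return "detour" if diff > config.detour_angle_deg else "none"


def summarize_encounter_rates(journeys: list[JourneySummary],
                              encounters: list[Encounter]) -> pd.DataFrame:
    """Per-population crossing counts, encounter counts and percentages."""
    enc_by_journey: dict[tuple[str, int], list[Encounter]] = {}
    for e in encounters:
        enc_by_journey.setdefault((e.bird_id, e.time.year), []).append(e)
    rows = []
    for pop in sorted({j.population or "unknown" for j in journeys}):
        js = [j for j in journeys if (j.population or "unknown") == pop]
        with_enc = [j for j in js if (j.bird_id, j.year) in enc_by_journey]
        encs = [e for j in js for e in enc_by_journey.get((j.bird_id, j.year), [])]
        n = len(js)
        k = len(with_enc)
        rows.append({
            "population": pop,
            "n_crossings": n,
            "n_with_encounter": k,
            "pct_with_encounter": int(round(100.0 * k / n)) if n else 0,
            "n_encounters": len(encs),
            "n_inflight": sum(e.bird_state == "in_flight" for e in encs),
            "n_grounded": sum(e.bird_state == "grounded" for e in encs),
        })
    return pd.DataFrame(rows)
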