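"""Readers/writers for the two external formats and the season/quality filters.

Telemetry arrives as a Movebank/ARGOS-style CSV of Doppler fixes, each tagged
with an ARGOS location class (LC).  Only LC 1-3 fixes (error < 1 km) are used
for analysis; LC 0/A/B/Z are parsed but filtered out downstream.

Cyclone best tracks use the NOAA/NHC HURDAT2 text format in its modern
(post-2013) comma-delimited dialect: a header line per storm
(``AL092011,              IRENE,     39,``) followed by the declared number of
data lines carrying date, time, record identifier, system status, latitude,
longitude with hemisphere suffix, max sustained wind in knots, and pressure /
wind-radii fields.  The writer emits byte-stable fixed widths so that
``parse(write(x)) == x`` and a second write is byte-identical.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")
# quality order, best first, for duplicate-timestamp resolution
_LC_RANK = {lc: i for i, lc in enumerate(LOCATION_CLASSES)}

STORM_STATUSES = ("TD", "TS", "HU", "EX", "SD", "SS", "LO", "WV", "DB")
# rank on the tropical ladder; non-tropical statuses have no rank
_TROPICAL_RANK = {"TD": 0, "TS": 1, "HU": 2}

MISSING_WIND = -99


class FormatError(ValueError):
    """Malformed external file (with file/line context in the message)."""


@dataclass(frozen=True)
class TrackPoint:
    bird_id: str
    timestamp: datetime
    lat: float
    lon: float
    location_class: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180.0 <= self.lon < 180.0:
            raise ValueError(f"longitude {self.lon} out of range")
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {self.location_class!r}")


@dataclass
class BirdTrack:
    """Ordered telemetry fixes for one individual."""

    bird_id: str
    points: list[TrackPoint]
    population: str | None = None  # 'MackenzieDelta' | 'HudsonBay'
    duty_cycle: tuple[float, float] | None = None  # (hours off, hours on)

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0

    @property
    def start(self) -> datetime:
        return self.points[0].timestamp

    @property
    def end(self) -> datetime:
        return self.points[-1].timestamp


@dataclass(frozen=True)
class StormPoint:
    storm_id: str
    name: str
    timestamp: datetime
    lat: float
    lon: float
    max_wind: int  # knots; MISSING_WIND if not reported
    status: str
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.status not in STORM_STATUSES:
            raise ValueError(f"unknown storm status {self.status!r}")
        if self.max_wind < 0 and self.max_wind != MISSING_WIND:
            raise ValueError("negative wind that is not the missing sentinel")

    @property
    def is_synoptic(self) -> bool:
        return self.timestamp.hour in (0, 6, 12, 18) and self.timestamp.minute == 0


@dataclass
class StormTrack:
    storm_id: str
    name: str
    points: list[StormPoint]


# ---------------------------------------------------------------------------
# telemetry CSV

DEFAULT_COLUMN_MAP = {
    "bird_id": "bird_id",
    "timestamp": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "location_class": "location_class",
    # optional
    "population": "population",
}


def parse_telemetry_csv(path, column_map: Mapping[str, str] | None = None
                        ) -> list[BirdTrack]:
    """Read an ARGOS-style fix table into one BirdTrack per individual.

    Rows are time-sorted per bird; duplicate (bird, timestamp) rows keep the
    best location class (tie: first row).  Rows with an unknown LC code are
    dropped with a warning; an unparseable timestamp raises with the line
    number.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str)
    required = ["bird_id", "timestamp", "lat", "lon", "location_class"]
    for key in required:
        if cmap[key] not in df.columns:
            raise FormatError(f"{path}: missing column {cmap[key]!r} (for {key})")
    if df.empty:
        return []

    ts = pd.to_datetime(df[cmap["timestamp"]], utc=True, errors="coerce")
    bad = ts.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise FormatError(
            f"{path}: unparseable timestamp "
            f"{df.loc[bad.idxmax(), cmap['timestamp']]!r} at line {line}")
    df = df.assign(_ts=ts.dt.tz_localize(None))

    lc = df[cmap["location_class"]].astype(str).str.strip().str.upper()
    known = lc.isin(LOCATION_CLASSES)
    if (~known).any():
        for idx in df.index[~known]:
            logger.warning("%s: line %d: unknown location class %r; row dropped",
                           path, idx + 2, lc.loc[idx])
        df = df[known]
        lc = lc[known]
    df = df.assign(_lc=lc, _rank=lc.map(_LC_RANK))

    tracks: list[BirdTrack] = []
    for bird_id, sub in df.groupby(cmap["bird_id"], sort=True):
        sub = sub.sort_values(["_ts", "_rank"], kind="stable")
        sub = sub.drop_duplicates(subset="_ts", keep="first")
        points = [
            TrackPoint(str(bird_id), t.to_pydatetime(), float(la), float(lo), c)
            for t, la, lo, c in zip(sub["_ts"], sub[cmap["lat"]].astype(float),
                                    sub[cmap["lon"]].astype(float), sub["_lc"])
        ]
        population = None
        if cmap.get("population") in sub.columns:
            vals = sub[cmap["population"]].dropna().unique()
            if len(vals):
                population = str(vals[0])
        tracks.append(BirdTrack(str(bird_id), points, population=population))
    return tracks


def write_telemetry_csv(tracks: Sequence[BirdTrack], path) -> None:
    """Inverse of parse_telemetry_csv (fixed precision, deterministic order)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bird_id", "timestamp", "lat", "lon", "location_class",
                    "population"])
        for tr in tracks:
            for p in tr.points:
                w.writerow([p.bird_id, p.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
                            f"{p.lat:.5f}", f"{p.lon:.5f}", p.location_class,
                            tr.population or ""])


def filter_by_location_class(track: BirdTrack,
                             allowed: Iterable[str] = ("1", "2", "3")
                             ) -> BirdTrack:
    """Keep only fixes whose ARGOS location class is in `allowed`.

    Order is preserved; the returned track may be empty (check ``is_empty``
    before feeding it to segmentation).
    """
    allowed = {str(a).upper() for a in allowed}
    if not allowed:
        raise ValueError("allowed set must be non-empty")
    unknown = allowed - set(LOCATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown location classes {sorted(unknown)}")
    kept = [p for p in track.points if p.location_class in allowed]
    if not kept:
        logger.warning("bird %s: no fixes left after LC filter", track.bird_id)
    return BirdTrack(track.bird_id, kept, population=track.population,
                     duty_cycle=track.duty_cycle)


# ---------------------------------------------------------------------------
# HURDAT2

def _parse_latlon(tok: str, line_no: int) -> float:
    tok = tok.strip()
    if not tok or tok[-1] not in "NSEW":
        raise FormatError(f"line {line_no}: malformed coordinate {tok!r}")
    try:
        val = float(tok[:-1])
    except ValueError as exc:
        raise FormatError(f"line {line_no}: malformed coordinate {tok!r}") from exc
    if tok[-1] in "SW":
        val = -val
    return val


def parse_hurdat2(path) -> list[StormTrack]:
    """Parse a HURDAT2 best-track file (modern comma-delimited dialect).

    The pre-2013 fixed-width dialect (no commas in data lines) is rejected
    with a clear error.  Raises FormatError when a storm's declared data-line
    count does not match the lines present.
    """
    storms: list[StormTrack] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        i += 1
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 3 or not (len(parts[0]) == 8 and parts[0][:2].isalpha()):
            raise FormatError(f"line {i}: expected a HURDAT2 header, got {line!r}"
                              " (pre-2013 fixed-width files are not supported)")
        storm_id, name = parts[0], parts[1]
        try:
            n_rows = int(parts[2])
        except ValueError as exc:
            raise FormatError(f"line {i}: bad entry count in header {line!r}") from exc
        points: list[StormPoint] = []
        for _ in range(n_rows):
            if i >= len(lines) or "," not in lines[i]:
                raise FormatError(
                    f"storm {storm_id}: declared {n_rows} data lines, found {len(points)}")
            row = [p.strip() for p in lines[i].split(",")]
            i += 1
            if len(row) < 8:
                raise FormatError(f"line {i}: too few fields in data line")
            if len(row[0]) == 8 and row[0][:2].isalpha() and not row[0].isdigit():
                raise FormatError(
                    f"storm {storm_id}: declared {n_rows} data lines, found {len(points)}")
            try:
                ts = datetime.strptime(row[0] + row[1], "%Y%m%d%H%M")
            except ValueError as exc:
                raise FormatError(f"line {i}: bad date/time {row[0]!r} {row[1]!r}") from exc
            status = row[3]
            lat = _parse_latlon(row[4], i)
            lon = _parse_latlon(row[5], i)
            try:
                wind = int(row[6])
            except ValueError as exc:
                raise FormatError(f"line {i}: bad wind {row[6]!r}") from exc
            points.append(StormPoint(storm_id, name, ts, lat, lon, wind, status,
                                     record_id=row[2]))
        storms.append(StormTrack(storm_id, name, points))
    return storms


def _fmt_latlon(val: float, is_lat: bool) -> str:
    if is_lat:
        if not -90.0 <= val <= 90.0:
            raise ValueError(f"latitude {val} out of range")
        hemi = "N" if val >= 0 else "S"
        return f"{abs(val):.1f}{hemi}"
    if not -180.0 <= val <= 180.0:
        raise ValueError(f"longitude {val} out of range")
    hemi = "E" if val >= 0 else "W"
    return f"{abs(val):.1f}{hemi}"


def write_hurdat2(storms: Sequence[StormTrack], path) -> None:
    """Write storms in the NHC comma-delimited dialect with fixed widths.

    Wind-radii fields (not modelled here) are written as the -999 missing
    sentinel.  Coordinates are rounded to 0.1 degree per the format.
    """
    with open(path, "w", newline="\n") as fh:
        for storm in storms:
            fh.write(f"{storm.storm_id:>8},{storm.name:>19},"
                     f"{len(storm.points):>7},\n")
            for p in storm.points:
                lat = _fmt_latlon(p.lat, True)
                lon = _fmt_latlon(p.lon, False)
                radii = ",".join(f"{-999:>5}" for _ in range(12))
                fh.write(
                    f"{p.timestamp:%Y%m%d}, {p.timestamp:%H%M},"
                    f"{p.record_id:>2},{p.status:>3},"
                    f"{lat:>6},{lon:>7},{p.max_wind:>4},{-999:>5},"
                    f"{radii},\n")


def storm_status_rank(status: str) -> int | None:
    """Rank on the TD < TS < HU ladder; None for non-tropical statuses."""
    return _TROPICAL_RANK.get(status)


def filter_storm_season(storms: Sequence[StormTrack],
                        start_monthday: tuple[int, int] = (7, 15),
                        end_monthday: tuple[int, int] = (11, 30),
                        year_min: int = 1961,
                        year_max: int = 2018,
                        min_status: str = "TD",
                        include_subtropical: bool = False
                        ) -> list[StormTrack]:
    """Season / era / intensity filter for the climatology.

    Retains storms with at least one qualifying point inside the seasonal
    window (month-day comparison within each year, inclusive) and year range;
    within each retained storm keeps only qualifying points.  A qualifying
    point is inside the window, has tropical status of rank >= ``min_status``
    (SD/SS count as TD/TS when ``include_subtropical``), and falls on a
    standard six-hourly synoptic time (00/06/12/18 UTC) so that every
    retained point carries equal lifespan weight.  Idempotent.
    """
    if min_status not in _TROPICAL_RANK:
        raise ValueError("min_status must be one of TD, TS, HU")
    min_rank = _TROPICAL_RANK[min_status]
    sub_rank = {"SD": 0, "SS": 1} if include_subtropical else {}

    def keep(p: StormPoint) -> bool:
        if not year_min <= p.timestamp.year <= year_max:
            return False
        md = (p.timestamp.month, p.timestamp.day)
        if not start_monthday <= md <= end_monthday:
            return False
        rank = _TROPICAL_RANK.get(p.status, sub_rank.get(p.status))
        if rank is None or rank < min_rank:
            return False
        return p.is_synoptic

    out: list[StormTrack] = []
    for storm in storms:
        pts = [p for p in storm.points if keep(p)]
        if pts:
            out.append(StormTrack(storm.storm_id, storm.name, pts))
    if not out:
        logger.warning("season filter removed every storm")
    return out
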