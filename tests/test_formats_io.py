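"""Telemetry CSV and HURDAT2 parsing/writing plus the quality/season filters."""

import dataclasses
from datetime import datetime

import pytest

from stormcross.formats_io import (FormatError, filter_by_location_class,
                                   filter_storm_season, parse_hurdat2,
                                   parse_telemetry_csv, write_hurdat2,
                                   write_telemetry_csv)
from stormcross.synthetic import (MACKENZIE_DELTA, ScenarioConfig,
                                  StormFieldConfig, generate_bird_tracks,
                                  generate_storm_basin)

from conftest import make_storm, make_track


# ---------------------------------------------------------------------------
# telemetry CSV


def test_empty_csv_yields_no_tracks(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("bird_id,timestamp,lat,lon,location_class\n")
    assert parse_telemetry_csv(p) == []


def test_rows_are_time_sorted_per_bird(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "bird_id,timestamp,lat,lon,location_class\n"
        "b1,2015-08-02T00:00:00Z,10,-60,3\n"
        "b1,2015-08-01T00:00:00Z,11,-61,2\n"
        "b1,2015-08-03T00:00:00Z,9,-59,1\n")
    (track,) = parse_telemetry_csv(p)
    assert len(track.points) == 3
    ts = [pt.timestamp for pt in track.points]
    assert ts == sorted(ts)
    assert track.points[0].lat == 11


def test_duplicate_timestamp_keeps_best_location_class(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "bird_id,timestamp,lat,lon,location_class\n"
        "b1,2015-08-01T00:00:00Z,10,-60,1\n"
        "b1,2015-08-01T00:00:00Z,11,-61,3\n"
        "b1,2015-08-01T00:00:00Z,12,-62,2\n")
    (track,) = parse_telemetry_csv(p)
    assert len(track.points) == 1
    assert track.points[0].location_class == "3"


def test_unknown_location_class_dropped(tmp_path, caplog):
    p = tmp_path / "t.csv"
    p.write_text(
        "bird_id,timestamp,lat,lon,location_class\n"
        "b1,2015-08-01T00:00:00Z,10,-60,3\n"
        "b1,2015-08-02T00:00:00Z,10,-60,Q\n")
    (track,) = parse_telemetry_csv(p)
    assert len(track.points) == 1


def test_bad_timestamp_reports_line_number(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "bird_id,timestamp,lat,lon,location_class\n"
        "b1,2015-08-01T00:00:00Z,10,-60,3\n"
        "b1,not-a-time,10,-60,3\n")
    with pytest.raises(FormatError, match="line 3"):
        parse_telemetry_csv(p)


def test_csv_roundtrip_preserves_generator_counts(tmp_path):
    cfg = ScenarioConfig(
        seed=5, journeys_per_bird=1,
        populations=(dataclasses.replace(MACKENZIE_DELTA, n_birds=2),))
    tracks, _ = generate_bird_tracks(cfg)
    path = tmp_path / "synthetic.csv"
    write_telemetry_csv(tracks, path)
    parsed = parse_telemetry_csv(path)
    assert len(parsed) == 2
    counts = {t.bird_id: len(t.points) for t in tracks}
    for t in parsed:
        assert len(t.points) == counts[t.bird_id]
        assert t.population == "MackenzieDelta"


# ---------------------------------------------------------------------------
# location-class filter


def test_lc_filter_keeps_only_allowed_classes():
    track = make_track("b", [(0, 1, 1, "3"), (1, 1, 1, "B"), (2, 1, 1, "1"),
                             (3, 1, 1, "0"), (4, 1, 1, "2")])
    out = filter_by_location_class(track, {"1", "2", "3"})
    assert [p.location_class for p in out.points] == ["3", "1", "2"]
    assert [p.timestamp for p in out.points] == sorted(
        p.timestamp for p in out.points)


def test_lc_filter_full_set_is_identity():
    track = make_track("b", [(0, 1, 1, "3"), (1, 1, 1, "B"), (2, 1, 1, "Z")])
    out = filter_by_location_class(track, "3210ABZ")
    assert out.points == track.points


def test_lc_filter_can_empty_a_track():
    track = make_track("b", [(0, 1, 1, "1"), (1, 1, 1, "2")])
    out = filter_by_location_class(track, {"3"})
    assert out.is_empty
    with pytest.raises(ValueError):
        filter_by_location_class(track, set())


# ---------------------------------------------------------------------------
# HURDAT2


def test_parse_toy_storm(tmp_path):
    p = tmp_path / "h.txt"
    p.write_text("AL092011,              IRENE,      1,\n"
                 "20110824, 1800,  , TD,  25.0N,  60.0W,  30, 1005,"
                 + " -999," * 11 + " -999,\n")
    (storm,) = parse_hurdat2(p)
    assert storm.storm_id == "AL092011"
    assert storm.name == "IRENE"
    pt = storm.points[0]
    assert (pt.lat, pt.lon, pt.status, pt.max_wind) == (25.0, -60.0, "TD", 30)
    assert pt.timestamp == datetime(2011, 8, 24, 18, 0)


def test_count_mismatch_raises(tmp_path):
    p = tmp_path / "h.txt"
    p.write_text("AL092011,              IRENE,      2,\n"
                 "20110824, 1800,  , TD,  25.0N,  60.0W,  30, 1005,\n")
    with pytest.raises(FormatError, match="AL092011"):
        parse_hurdat2(p)


def test_malformed_coordinate_raises(tmp_path):
    p = tmp_path / "h.txt"
    p.write_text("AL092011,              IRENE,      1,\n"
                 "20110824, 1800,  , TD,  25.0X,  60.0W,  30, 1005,\n")
    with pytest.raises(FormatError, match="line"):
        parse_hurdat2(p)


def test_write_empty_and_line_arithmetic(tmp_path):
    p = tmp_path / "h.txt"
    write_hurdat2([], p)
    assert p.read_text() == ""
    storm = make_storm("AL012015", [(0, 20.0, -60.0, 40), (6, 20.5, -61.0, 45)])
    write_hurdat2([storm], p)
    assert len(p.read_text().splitlines()) == 3


def test_write_refuses_out_of_range(tmp_path):
    storm = make_storm("AL012015", [(0, 20.0, -60.0, 40)])
    bad = dataclasses.replace(storm.points[0], lat=95.0)
    storm.points[0] = bad
    with pytest.raises(ValueError):
        write_hurdat2([storm], tmp_path / "h.txt")


def test_hurdat2_roundtrip_identity_and_fixpoint(tmp_path):
    cfg = ScenarioConfig(seed=11, storm_field=StormFieldConfig(n_storms=10))
    storms, _ = generate_storm_basin(cfg)
    assert len(storms) == 10
    p1 = tmp_path / "a.txt"
    p2 = tmp_path / "b.txt"
    write_hurdat2(storms, p1)
    parsed = parse_hurdat2(p1)
    assert len(parsed) == 10
    assert [len(s.points) for s in parsed] == [len(s.points) for s in storms]
    for s, q in zip(storms, parsed):
        assert (s.storm_id, s.name) == (q.storm_id, q.name)
        for a, b in zip(s.points, q.points):
            assert (a.timestamp, a.lat, a.lon, a.max_wind, a.status) == \
                   (b.timestamp, b.lat, b.lon, b.max_wind, b.status)
    write_hurdat2(parsed, p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# season filter


def test_june_storm_excluded():
    storm = make_storm("AL011990", [(0, 15, -40, 30)])
    june = dataclasses.replace(storm.points[0],
                               timestamp=datetime(1990, 6, 10, 12, 0))
    storm.points[0] = june
    assert filter_storm_season([storm], year_min=1961, year_max=2018) == []


def test_status_ladder_and_min_status():
    recs = [(0, 15, -40, 25, "LO"), (6, 15, -41, 30, "TD"),
            (12, 15, -42, 40, "TS"), (18, 16, -43, 40, "EX")]
    storm = make_storm("AL012015", recs)
    out = filter_storm_season([storm], year_min=2015, year_max=2015)
    assert [p.status for p in out[0].points] == ["TD", "TS"]
    out_ts = filter_storm_season([storm], year_min=2015, year_max=2015,
                                 min_status="TS")
    assert [p.status for p in out_ts[0].points] == ["TS"]


def test_subtropical_excluded_by_default():
    storm = make_storm("AL012015", [(0, 15, -40, 30, "SD"),
                                    (6, 15, -41, 40, "SS")])
    assert filter_storm_season([storm], year_min=2015, year_max=2015) == []
    out = filter_storm_season([storm], year_min=2015, year_max=2015,
                              include_subtropical=True)
    assert len(out[0].points) == 2


def test_off_synoptic_points_dropped():
    storm = make_storm("AL012015", [(0, 15, -40, 30), (3, 15, -40.5, 30),
                                    (6, 15, -41, 30)])
    out = filter_storm_season([storm], year_min=2015, year_max=2015)
    assert len(out[0].points) == 2


def test_season_filter_matches_row_scan_oracle_and_is_idempotent():
    cfg = ScenarioConfig(seed=3, storm_field=StormFieldConfig(
        n_storms=15, year_min=2010, year_max=2016))
    storms, _ = generate_storm_basin(cfg)
    out = filter_storm_season(storms, year_min=2010, year_max=2016)

    def keep(p):  # independent brute-force row filter
        md_ok = (7, 15) <= (p.timestamp.month, p.timestamp.day) <= (11, 30)
        yr_ok = 2010 <= p.timestamp.year <= 2016
        st_ok = p.status in ("TD", "TS", "HU")
        syn = p.timestamp.hour in (0, 6, 12, 18) and p.timestamp.minute == 0
        return md_ok and yr_ok and st_ok and syn

    expected = sum(keep(p) for s in storms for p in s.points)
    got = sum(len(s.points) for s in out)
    assert got == expected
    twice = filter_storm_season(out, year_min=2010, year_max=2016)
    assert sum(len(s.points) for s in twice) == got
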