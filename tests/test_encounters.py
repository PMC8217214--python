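"""Encounter detection, intensity classification and response taxonomy."""

from datetime import timedelta

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, box

from stormcross.encounters import (EncounterConfig, classify_response,
                                   detect_grounded_encounters,
                                   detect_inflight_encounters,
                                   saffir_simpson_category,
                                   summarize_encounter_rates)
from stormcross.formats_io import BirdTrack, TrackPoint
from stormcross.migration import JourneySummary, Phase, detect_residency

from conftest import T0, make_storm, make_track


# ---------------------------------------------------------------------------
# Saffir-Simpson scale


@pytest.mark.parametrize("mph,label", [
    (0, "TD"), (38, "TD"), (38.9, "TD"),
    (39, "TS"), (73, "TS"),
    (74, "C1"), (95, "C1"),
    (96, "C2"), (110, "C2"),
    (111, "C3"), (129, "C3"),
    (130, "C4"), (140, "C4"), (156, "C4"),
    (157, "C5"), (200, "C5"),
])
def test_saffir_simpson_band_edges(mph, label):
    assert saffir_simpson_category(mph) == label


def test_saffir_simpson_rejects_negative():
    with pytest.raises(ValueError):
        saffir_simpson_category(-1.0)


def test_saffir_simpson_monotone_step():
    winds = np.linspace(0, 200, 2001)
    order = ["TD", "TS", "C1", "C2", "C3", "C4", "C5"]
    ranks = [order.index(saffir_simpson_category(w)) for w in winds]
    assert ranks == sorted(ranks)


# ---------------------------------------------------------------------------
# in-flight detection


def _crossing_scene(offset_km=50.0, lon_shift=0.0, storm_moves=False):
    """Bird flying south along a meridian past a storm centre.

    With a stationary storm the minimum separation is exactly offset_km,
    reached when the bird passes the storm's latitude at T0+48h.
    """
    lon = -60.0 + lon_shift
    bird = make_track("b", [(h, 30.0 - h * 0.25, lon) for h in range(0, 97, 6)])
    # offset due east of the bird's path, measured along the lat-18 parallel
    off_deg = offset_km / (111.19508 * np.cos(np.deg2rad(18.0)))
    drift = 0.25 if storm_moves else 0.0
    storm = make_storm("AL012015", [
        (h, 18.0, lon + off_deg + (48 - h) * drift, 50)
        for h in range(0, 97, 6)])
    t_star = T0 + timedelta(hours=48)
    return bird, storm, t_star


def test_no_storms_no_encounters():
    bird, _, _ = _crossing_scene()
    assert detect_inflight_encounters(bird, []) == []


def test_planted_crossing_detected_once_at_right_time():
    bird, storm, t_star = _crossing_scene(offset_km=50.0)
    cfg = EncounterConfig()
    encs = detect_inflight_encounters(bird, [storm], cfg)
    assert len(encs) == 1
    e = encs[0]
    assert abs((e.time - t_star).total_seconds()) <= cfg.sync_step_min * 60.0
    assert e.min_separation_km == pytest.approx(50.0, abs=10.0)
    assert e.bird_state == "in_flight"
    # 50 kt * 1.15078 = 57.5 mph -> tropical storm
    assert e.storm_category == "TS"


def test_temporal_mismatch_is_no_encounter():
    bird, storm, _ = _crossing_scene()
    late = make_storm(storm.storm_id, [])
    late.points = [type(p)(p.storm_id, p.name,
                           p.timestamp + timedelta(days=10), p.lat, p.lon,
                           p.max_wind, p.status, p.record_id)
                   for p in storm.points]
    assert detect_inflight_encounters(bird, [late]) == []


def test_encounter_counts_monotone_in_radius():
    bird, storm, _ = _crossing_scene(offset_km=350.0, storm_moves=True)
    counts = []
    for radius in (50.0, 200.0, 300.0, 400.0, 500.0):
        cfg = EncounterConfig(encounter_radius_km=radius)
        counts.append(len(detect_inflight_encounters(bird, [storm], cfg)))
    assert counts == sorted(counts)
    assert counts[0] == 0 and counts[-1] == 1


def test_detection_invariant_under_longitude_shift():
    for shift in (0.0, 25.0, 60.0):
        bird, storm, _ = _crossing_scene(offset_km=80.0, lon_shift=shift)
        encs = detect_inflight_encounters(bird, [storm])
        assert len(encs) == 1
        assert encs[0].min_separation_km == pytest.approx(80.0, abs=12.0)


# ---------------------------------------------------------------------------
# grounded detection


def _grounded_phase(lat=18.0, lon=-66.0, days=15):
    return Phase("staging", T0, T0 + timedelta(days=days), (lat, lon),
                 list(range(days)), radius_km=50.0)


def test_storm_over_grounded_bird():
    phase = _grounded_phase()
    off = 20.0 / 111.19508
    storm = make_storm("AL012015", [
        (24 + h, 18.0 + off, -60.0 - h * 0.25, 45) for h in range(0, 49, 6)])
    encs = detect_grounded_encounters(phase, "b", [storm])
    assert len(encs) == 1
    assert encs[0].bird_state == "grounded"
    assert encs[0].min_separation_km <= 25.0


def test_distant_storm_not_an_encounter():
    phase = _grounded_phase()
    storm = make_storm("AL012015", [
        (24 + h, 22.5, -60.0 - h * 0.25, 45) for h in range(0, 49, 6)])  # ~500 km
    assert detect_grounded_encounters(phase, "b", [storm]) == []


def test_two_storms_two_encounters():
    phase = _grounded_phase(days=30)
    off = 30.0 / 111.19508
    s1 = make_storm("AL012015", [
        (24 + h, 18.0 + off, -60.0 - h * 0.25, 60) for h in range(0, 49, 6)])
    s2 = make_storm("AL022015", [
        (240 + h, 18.0 - off, -60.0 - h * 0.25, 45) for h in range(0, 49, 6)])
    encs = detect_grounded_encounters(phase, "b", [s1, s2])
    assert [e.storm_id for e in encs] == ["AL012015", "AL022015"]


# ---------------------------------------------------------------------------
# responses


ISLANDS = MultiPolygon([box(-66.6, 17.9, -65.6, 18.9)])


def _enc_at(track, t, lat, lon):
    from stormcross.encounters import Encounter
    return Encounter("b", "AL012015", "TEST", t, lat, lon, "in_flight", "TS",
                     50.0)


def test_straight_track_is_no_response():
    bird = make_track("b", [(h, 30.0 - 0.25 * h, -60.0) for h in range(0, 97, 3)])
    e = _enc_at(bird, T0 + timedelta(hours=48), 18.0, -60.0)
    assert classify_response(bird, e, ISLANDS) == "none"


def test_turn_beyond_threshold_is_detour():
    # southbound, then a ~40 degree turn right after hour 48
    pts = [(h, 30.0 - 0.25 * h, -60.0) for h in range(0, 49, 3)]
    lat0 = 30.0 - 0.25 * 48
    pts += [(h, lat0 - 0.20 * (h - 48), -60.0 - 0.17 * (h - 48))
            for h in range(51, 97, 3)]
    bird = make_track("b", pts)
    e = _enc_at(bird, T0 + timedelta(hours=48), lat0, -60.0)
    assert classify_response(bird, e, ISLANDS) == "detour"


def test_landing_on_island_is_grounded_and_supersedes():
    pts = [(h, 30.0 - 0.3 * h, -66.1) for h in range(0, 40, 3)]
    # stationary on the island from ~hour 40 for 10 days
    pts += [(40 + 6 * k, 18.3, -66.1) for k in range(40)]
    bird = make_track("b", pts)
    e = _enc_at(bird, T0 + timedelta(hours=36), 19.2, -66.1)
    assert classify_response(bird, e, ISLANDS) == "grounded"


def test_truncated_track_is_indeterminate():
    bird = make_track("b", [(h, 30.0 - 0.25 * h, -60.0) for h in range(0, 49, 3)])
    e = _enc_at(bird, T0 + timedelta(hours=48), 18.0, -60.0)
    assert classify_response(bird, e, ISLANDS) == "indeterminate"


# ---------------------------------------------------------------------------
# rate summaries


def _journeys(pop, n, n_with, yr0=2008):
    out = []
    for i in range(n):
        out.append(JourneySummary(
            bird_id=f"{pop[:2]}{i}", population=pop, year=yr0 + i % 5,
            departure_date=T0, arrival_date=T0 + timedelta(days=30),
            total_distance=9000.0, duration=30.0, rate_of_advance=300.0))
    return out


def test_rate_table_matches_printed_percentages():
    md = _journeys("MackenzieDelta", 26, 3)
    hb = _journeys("HudsonBay", 21, 13)
    from stormcross.encounters import Encounter
    encs = []
    for j in md[:3] + hb[:13]:
        encs.append(Encounter(j.bird_id, "AL012015", "TEST",
                              T0.replace(year=j.year) + timedelta(days=5),
                              18.0, -60.0, "in_flight", "TS", 50.0))
    tab = summarize_encounter_rates(md + hb, encs).set_index("population")
    assert tab.loc["MackenzieDelta", "pct_with_encounter"] == 12
    assert tab.loc["MackenzieDelta", "n_with_encounter"] == 3
    assert tab.loc["HudsonBay", "pct_with_encounter"] == 62
    assert tab.loc["HudsonBay", "n_with_encounter"] == 13


def test_rate_table_zero_encounters():
    md = _journeys("MackenzieDelta", 10, 0)
    tab = summarize_encounter_rates(md, []).set_index("population")
    assert tab.loc["MackenzieDelta", "pct_with_encounter"] == 0
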