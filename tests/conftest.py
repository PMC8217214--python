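"""Shared fixtures: tiny deterministic tracks, storms and scenarios."""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta

import numpy as np
import pytest

from stormcross.formats_io import (BirdTrack, StormPoint, StormTrack,
                                   TrackPoint)
from stormcross.synthetic import (HUDSON_BAY, MACKENZIE_DELTA, ScenarioConfig,
                                  StormFieldConfig)

T0 = datetime(2015, 8, 1, 0, 0, 0)


def make_track(bird_id, fixes, population=None):
    """fixes: list of (hours_from_T0, lat, lon[, lc])."""
    pts = []
    for f in fixes:
        h, lat, lon = f[:3]
        lc = f[3] if len(f) > 3 else "3"
        pts.append(TrackPoint(bird_id, T0 + timedelta(hours=float(h)),
                              float(lat), float(lon), lc))
    return BirdTrack(bird_id, pts, population=population)


def make_storm(storm_id, records, name="TEST"):
    """records: list of (hours_from_T0, lat, lon, wind_kt[, status])."""
    pts = []
    for r in records:
        h, lat, lon, wind = r[:4]
        status = r[4] if len(r) > 4 else ("TD" if wind < 34 else
                                          "TS" if wind < 64 else "HU")
        pts.append(StormPoint(storm_id, name, T0 + timedelta(hours=float(h)),
                              float(lat), float(lon), int(wind), status))
    return StormTrack(storm_id, name, pts)


@pytest.fixture(scope="session")
def small_scenario_config():
    """A reduced two-population scenario for fast end-to-end tests."""
    return ScenarioConfig(
        seed=7,
        populations=(dataclasses.replace(MACKENZIE_DELTA, n_birds=4),
                     dataclasses.replace(HUDSON_BAY, n_birds=4)),
        journeys_per_bird=1,
        storm_field=StormFieldConfig(n_storms=12, year_min=2012, year_max=2015),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
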