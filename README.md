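# stormcross

Trans-Atlantic bird migration tracks versus tropical-cyclone climatology:
exposure, encounters, and inference.

Millions of shorebirds cross the western Atlantic each autumn at the peak of
hurricane season. Whimbrels (*Numenius phaeopus hudsonicus*) from two
breeding populations take contrasting routes: a long offshore crossing from
Atlantic Canada that skirts the core of storm activity, and a shorter
crossing from the south Atlantic coast straight through "hurricane alley"
and the West Indies. `stormcross` is a tested, reusable pipeline for
quantifying what those route choices mean: it ingests satellite-telemetry
fix tables and NOAA HURDAT2 best tracks, builds the seasonal cyclone-risk
region, measures each journey's time inside it, detects and classifies
bird × storm encounters, and runs the comparative statistics — with a
ground-truthed synthetic-data generator so every stage is testable without
any external downloads.

## What it computes

* **Ingest & filters** — ARGOS-style telemetry (location classes 1–3
  retained) and HURDAT2 text (read *and* write, byte-stable); seasonal
  storm filter (15 Jul–30 Nov, 1961–2018, tropical depression or above,
  synoptic records only).
* **Geodesy** — great-circle distance/bearing/interpolation, and
  fixed-speed boundary-crossing interpolation: crossing instants are placed
  at `t_fix ± d/v̄` with v̄ = 14.8 m/s, the cohort-mean flight speed.
* **Migration phases** — stationary-territory detection (50 km / 7 days),
  departure & arrival instants, trans-oceanic segmentation with
  coast-crossing interpolation, per-journey summaries (distance, duration,
  rate of advance, ocean departure latitude).
* **Cyclone climatology** — one unit-weight point per six-hourly record
  (storms weighted by lifespan), Gaussian KDE in a Lambert equal-area plane
  (plug-in, SCV, or fixed bandwidth), and the 50% highest-density region
  ("core cyclone area") as exact grid-quantile superlevel-set polygons.
* **Exposure** — per-journey time inside the risk region, entry/exit
  interpolated at fixed speed, multiple excursions summed, grounded time
  counted in full.
* **Encounters** — spatiotemporal intersection of interpolated bird and
  storm trajectories on a shared 30-min grid (default radius 300 km;
  grounded radius 100 km), Saffir–Simpson intensity at encounter
  (TD ≤ 38 … C5 ≥ 157 mph, knots × 1.15078), response taxonomy
  none / detour (> 20° deflection) / grounding on an island.
* **Statistics** — two-sample t-tests from printed summaries (pooled df =
  n₁+n₂−2, Welch optional), G-tests with Yates correction, random-intercept
  logistic regression via adaptive Gauss–Hermite quadrature with
  singular-fit detection, and AICc model ranking with the 2-ΔAICc rule.

## Worked example

Run the built-in synthetic scenario — two populations with the field
cohorts' route parameters, a 30-storm basin, and planted encounters — and
print the results bundle:

```sh
stormcross run --seed 3 --out results/run0
```

The report (`results/run0/report.md`) contains, among other tables:

```
## Exposure to the high-risk region (days)
- HudsonBay: 0.31 +/- 0.10 SE (n = 22)
- MackenzieDelta: 0.00 +/- 0.00 SE (n = 26)

## Encounter rates
- HudsonBay: 14 (64%) of 22 crossings with >= 1 encounter; 14 in flight, 0 grounded
- MackenzieDelta: 2 (8%) of 26 crossings with >= 1 encounter; 2 in flight, 0 grounded

## Statistics
- encounter frequency: HudsonBay vs MackenzieDelta: G-test (Yates), statistic = 15.29, df = 1, p = 9.21e-05
- encounter likelihood ~ population (random intercept: year): mixed logit (adaptive GH), statistic = -3.80, p = 0.000146
```

Reading: journeys on the southern, island-arc route spend measurably more
time inside the 50% storm-density region and encounter storms on 64% of
crossings versus 8% on the offshore route; the population effect on
encounter likelihood is strongly supported both by the frequency comparison
and by the mixed model with a year random intercept. (Numbers are for the
synthetic scenario at seed 3 — the generator's planted risk contrast, not a
re-analysis of field data.)

Library use mirrors the CLI:

```python
from stormcross import (GroupSummary, t_test_from_summary,
                        saffir_simpson_category)

t_test_from_summary(GroupSummary(11012, 72.4, 14),
                    GroupSummary(8404, 76.0, 13))
# TestResult(statistic=24.857..., df=25.0, p_value=3.79e-19, method='t-test (pooled)')
saffir_simpson_category(140.0)   # 'C4'
```

Other CLI verbs: `stormcross synth` (write a ground-truthed scenario as
telemetry CSV + HURDAT2 + islands GeoJSON), `stormcross ingest`,
`stormcross climatology --hurdat f --years 1961:2018 --mass 0.5`, and
`stormcross config` (print every default, including the paper-gap choices
such as the encounter radius, so they are visible and citable).

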