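# firepm25

Near-real-time estimation of PM2.5 emissions from biomass burning in
Northern Thailand, from satellite active-fire detections to
decision-support products.

Seasonal agricultural and forest burning over the eight provinces of
upper Northern Thailand (Chiang Mai, Chiang Rai, Lampang, Lamphun,
Mae Hong Son, Nan, Phayao, Phrae) drives severe haze episodes every
January–April. This package implements the full estimation chain used to
quantify that source on a daily cadence:

1. **Ingest** — parse MODIS (MCD14DL) and VIIRS (VNP14IMGTDL) active-fire
   CSV tables, normalize the two confidence conventions, retain
   detections with confidence ≥ 80%, fuse duplicate observations of the
   same fire (within 500 m and 24 h, keeping the highest-confidence
   record), and clip to the region of interest.
2. **Burned area** — give each surviving detection its nominal sensor
   footprint (MODIS 1.0 km², VIIRS 375 m ⇒ 0.140625 km²) as a square in a
   regional equal-area projection, and merge overlapping footprints from
   the same local civil day (UTC+7) into fire events by polygon union, so
   overlapping observations are never double-counted.
3. **Fuel model** — assign each event the majority IGBP land-cover class
   under its polygon and look up fuel loading B (kg m⁻²), combustion
   completeness C, and the PM2.5 emission factor EF (g kg⁻¹) from a
   per-class table.
4. **Emission** — apply the fire-inventory equation per event:
   `E = A × B × C × EF`, with A the event area. In practical units,
   tons of PM2.5 = area_km2 · B · C · EF exactly. Event masses are
   spread onto a 0.01° grid proportionally to polygon–cell overlap area;
   total mass is conserved to rounding error.
5. **Aggregate** — daily, cumulative and monthly series; totals, shares
   and per-km² densities by subdistrict, district, province and region;
   forest/agriculture splits.
6. **Analytics** — Pearson correlation of emissions against fire
   radiative power, OLS regression of regional-mean PM2.5 on the daily
   emission rate (Y = α + βX), and inversion of that regression at a
   target concentration to obtain the **Emission Control Threshold**: the
   maximum daily emission load (floored to whole tons, the
   health-protective direction) compatible with keeping PM2.5 at or below
   the target. The threshold drives an exceedance calendar and
   burn-permit screening.
7. **Synthetic scenarios** — a seeded generator producing a full fake
   fire season (land cover, administrative polygons, dual-sensor
   detections with jitter and duplicates, station PM2.5) together with a
   ground-truth ledger, so the whole chain can be validated end-to-end.

With the published 2024-season regression (α = 40.41 µg m⁻³,
β = 6.31343 × 10⁻⁶ µg m⁻³ per kg day⁻¹) and the Thai 24-h PM2.5 standard
of 50 µg m⁻³, the Emission Control Threshold evaluates to
**1,518 tons/day**:

```console
$ firepm25 analyze --landcover lc.tif --admin admin.geojson --out out \
    --reference-coefficients
{"threshold_tons_day": 1518.0, "y_target_ug_m3": 50.0, "source": "published 2024-season regression"}
```

## Worked example

Generate a synthetic 2024 season on the default 2.0° × 1.6° domain and
run the full pipeline on its file products:

```console
$ firepm25 simulate --seed 7 --out scenario
{
 "landcover": "scenario/landcover.tif",
 "admin": "scenario/admin.geojson",
 "fuel": "scenario/fuel_parameters.csv",
 "pm25": "scenario/stations_pm25.csv",
 "fires_truth": "scenario/truth_fires.csv",
 "obs_truth": "scenario/truth_observations.csv",
 "MODIS": "scenario/detections_modis.csv",
 "VIIRS": "scenario/detections_viirs.csv"
}

$ firepm25 run-all \
    --modis scenario/detections_modis.csv \
    --viirs scenario/detections_viirs.csv \
    --landcover scenario/landcover.tif \
    --admin scenario/admin.geojson \
    --fuel scenario/fuel_parameters.csv \
    --pm25 scenario/stations_pm25.csv \
    --out products
{"n_detections": 2581, "n_events": 2174, "total_pm25_tons": 47432.70733724932, "threshold_tons_day": 922.0, "n_exceed": 8}
```

The run takes ~12 s on one CPU. The QC log records every stage:
3,759 raw detections → 3,491 after the confidence filter → 2,587 after
duplicate fusion → 2,581 inside the region, merged into 2,174 daily fire
events. `products/` then contains per-day GeoTIFF rasters, a NetCDF
time × lat × lon stack, the event polygons as GeoJSON, per-event and
daily CSV tables, admin summaries at all four levels, the analytics
report, the exceedance calendar, and a provenance record (configuration
and SHA-256 digests of every input). `products/analytics.json` for this
run:

```json
{
    "n_events": 2174,
    "total_pm25_tons": 47432.70733724932,
    "regression": {
        "alpha_ug_m3": 39.12662009017643,
        "beta_ug_m3_per_x": 1.178482321330934e-05,
        "x_unit": "kg/day",
        "r": 0.5675362141320746,
        "r2": 0.322097354351368,
        "p_slope": 1.138835036691985e-11,
        "n_days": 121
    },
    "emission_control_threshold": {
        "y_target_ug_m3": 50.0,
        "x_star_tons_day": 922.0
    },
    "exceedance": {"n_exceed": 8, "n_days": 121, "runs": [3, 2, 1, 2]},
    "frp_emission_daily_r": 0.8840241882264922
}
```

Because the scenario ships a ground-truth ledger, recovery can be
checked: the pipeline's daily emission series correlates with the true
daily emitted mass at r = 0.93 for this seed. The absolute total
(47,433 t estimated vs 79,205 t true) differs because the pipeline
measures *nominal footprint* area, not the true burned area — the
same structural bias the operational system has; see
`docs/methods.md`.

The same chain is available as a library:

```python
from firepm25.pipeline import RunConfig, run

result = run("scenario/detections_modis.csv", "scenario/detections_viirs.csv",
             "scenario/landcover.tif", "scenario/admin.geojson",
             "scenario/fuel_parameters.csv", RunConfig(),
             pm25_csv="scenario/stations_pm25.csv")
print(result.threshold.x_star, result.exceedance["n_exceed"])
```

## Layout

- `src/firepm25/` — the library: `detections` (ingest/QC), `burnarea`
  (footprints, events), `landcover` (IGBP classes, fuel parameters),
  `emission` (E = A·B·C·EF, gridding), `aggregate`, `analytics`,
  `simulate` (scenario generator), `pipeline`, `products`, `cli`,
  plus `proj` (equal-area projection) and `raster` (GeoTIFF I/O).
- `tests/` — property- and oracle-based suite.
- `scripts/acceptance.py` — recomputes the headline quantities.
- `docs/methods.md` — models, parameter defaults, numerical choices and
  limitations.
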