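# Methods

This note documents the models implemented in `firepm25`, the default
parameter values and the rationale behind them, the scope of the
synthetic-scenario generator, the numerical choices that affect results,
and the known limitations.

## 1. Detection ingest and quality control

**Inputs.** Active-fire CSV tables in the two operational dialects:
MODIS (MCD14DL: `latitude, longitude, brightness, scan, track, acq_date,
acq_time, satellite, instrument, confidence, version, bright_t31, frp,
daynight`) and VIIRS 375 m (VNP14IMGTDL: same layout with `bright_ti4`,
`bright_ti5` and a categorical confidence). Mandatory fields are
latitude, longitude, acquisition date/time (`HHMM` UTC), confidence and
fire radiative power (FRP, MW). Malformed rows are logged with a row
number and message and skipped; a bad row never aborts a run.

**Confidence normalization.** MODIS confidence is already a 0–100
percentage. VIIRS categorical classes are mapped `l → 30`, `n → 80`,
`h → 100`. The mapping puts `n` exactly at the operational cut-off so
nominal-confidence VIIRS pixels are retained, mirroring practice of
treating nominal and high VIIRS detections as usable.

**Confidence filter.** Detections with normalized confidence < 80% are
discarded. The filter is order-preserving and monotone in the cut-off.

**Duplicate fusion.** The two sensors (and successive overpasses) see
the same fire more than once. Detections within 500 m *and* 24 h of a
kept detection are suppressed, greedily: candidates are ranked by
(confidence ↓, FRP ↓, VIIRS before MODIS, id ↑) and each kept detection
suppresses its neighborhood. Distances are exact great-circle
(haversine) distances; a k-d tree on projected coordinates (query radius
padded ×1.05 + 10 m to cover projection distortion) only prefilters the
candidate pairs, so the result is identical to the O(n²) definition —
the test suite verifies exact agreement with a brute-force oracle.

**Region clip.** Detections are kept when covered by a subdistrict
polygon of the administrative mask. A point on a shared boundary is
assigned to the polygon with the smallest subdistrict code —
deterministic, order-independent and double-count-free.

## 2. Burned-area events

Each detection contributes its nominal footprint: an axis-aligned square
in the regional equal-area projection, centred on the detection, with
side 1,000 m for MODIS (1.0 km²) and 375 m for VIIRS (0.140625 km²,
printed as 0.14 elsewhere). Nominal footprints are used because neither
product measures the within-pixel burned fraction; this overestimates
small fires and underestimates area for fires larger than a pixel
(§ Limitations).

Footprints from the same *local civil day* (UTC+7; an overpass at
17:05 UTC already belongs to the next local day) whose polygons overlap
are merged by union-find into fire events; the event geometry is the
polygon union, so the overlapping area is counted once. `gap_tol_m`
(default 0) optionally buffers footprints before the overlap test to
bridge small gaps. Event area is the union area in the equal-area frame;
FRP is summed over members.

**Projection.** A spherical Albers equal-area conic (authalic radius
6,371,007.181 m, central meridian 99° E, origin 19° N, standard
parallels 17.5° N / 20.5° N) centred on the study region. Equal-area by
construction, so polygon areas in the projected frame are true areas; at
regional scale the spherical-vs-ellipsoidal area difference is well
below the footprint quantization error. Forward/inverse round-trips are
accurate to ~1e-14 degrees.

## 3. Land cover and fuel parameters

Events are assigned the IGBP class (17-class scheme) holding the largest
projected-area share of the event polygon, computed by intersecting the
polygon with the land-cover cells in the equal-area frame. Ties within a
1e-9 relative tolerance resolve to the class with the larger emission
potential B·C·EF (conservative for a health-protective product), then to
the smaller class id. An event entirely over no-data is a geometry
error.

Default per-class parameters (editable via a CSV with columns
`lc_class, B_kg_m2, C_frac, EF_g_kg, burnable`):

| IGBP class | B (kg m⁻²) | C | EF (g kg⁻¹) |
|---|---|---|---|
| 1 evergreen needleleaf | 12.0 | 0.45 | 15.3 |
| 2 evergreen broadleaf | 28.0 | 0.50 | 9.1 |
| 3 deciduous needleleaf | 12.0 | 0.45 | 15.3 |
| 4 deciduous broadleaf | 13.5 | 0.45 | 9.1 |
| 5 mixed forest | 13.0 | 0.45 | 12.2 |
| 6 closed shrubland | 5.0 | 0.55 | 9.3 |
| 7 open shrubland | 2.0 | 0.55 | 9.3 |
| 8 woody savanna | 4.0 | 0.60 | 9.3 |
| 9 savanna | 0.9 | 0.85 | 8.5 |
| 10 grassland | 0.5 | 0.90 | 7.2 |
| 11 permanent wetland | 0.8 | 0.40 | 9.4 |
| 12 cropland | 0.5 | 0.90 | 8.3 |
| 14 cropland/natural mosaic | 0.7 | 0.80 | 8.3 |
| 13, 15, 16, 17 | — | — | non-burnable |

These follow the fire-inventory convention for tropical/subtropical
Asia: heavy fuel loads and moderate completeness in forests, light loads
with near-complete combustion in croplands and grasslands; urban, snow,
barren and water are non-burnable (a detection there is an emission of
zero, flagged, not an error). A loaded table is validated: classes 1–17
complete, B > 0, 0 < C ≤ 1, EF > 0 for every burnable class. Land-use
groups used in reporting: forest = {1–5, 8, 9}, agriculture = {12, 14}.

## 4. Emission model

Per event, the standard fire-emission identity

  E_PM2.5 = A × B × C × EF

with A the event area (km² → m²), giving grams; in reporting units the
identity collapses exactly to `tons = area_km2 · B · C · EF`. The
arithmetic is checked dimensionally in the tests (1 km² × 1 kg m⁻² ×
1 × 10 g kg⁻¹ = 10 t) and is linear and monotone in each factor.

**Gridding.** Daily event masses are spread over a 0.01° (~1 km)
lat/lon grid: each event's mass is split across the cells its polygon
intersects, proportionally to the intersection areas computed in the
equal-area frame, with the weights normalized per event so the gridded
total equals the event total identically (conservation ≈ 1e-15 relative
in practice, 1e-6 asserted). An event outside the grid is an error, not
silent mass loss. The FRP field is gridded the same way for the
spatial FRP–emission diagnostics.

## 5. Aggregation

Emission records aggregate by exact code prefix: subdistrict (6-digit
code) → district (4) → province (2) → region. Per-level tables carry
tons, area, density (t km⁻²) and share of the regional total; the
hierarchy conserves mass exactly. Time aggregation gives daily,
cumulative and calendar-month series (January–April season = 4 months).
Densities and land-use intensities are plain quotients: the published
2024 provincial figures — regional total 271,551 t; densities such as
Mae Hong Son 5.42 and Chiang Mai 3.17 t km⁻²; forest intensities 5.86
and 4.15; agricultural intensities 3.27 and 0.56; shares 25.8% + 25.5%
= 51.3%; Lamphun 8,236 t over 4 months ⇒ 2,059 t/month — are reproduced
from the printed tons and km² by these exact formulas in the tests.

## 6. Analytics and the Emission Control Threshold

Daily regional-mean PM2.5 (unweighted mean over retained stations) is
regressed on the daily emission rate by OLS: Y = α + βX, with X in
kg/day by default (matching the published coefficient scale). The fit
reports α, β, Pearson r, R², the slope's two-sided p-value and 95%
confidence intervals.

The threshold inverts the fit at a target concentration Y* (default the
Thai 24-h standard, 50 µg m⁻³):

  X* = floor[ (Y* − α) / β ]  (in tons/day)

Flooring is the health-protective rounding: operating at X* keeps the
predicted concentration at or below the target. With the published
coefficients α = 40.41 and β = 6.31343e-6 per kg, (50 − 40.41)/β =
1,518,985 kg/day ⇒ **X\* = 1,518 t/day**. Before flooring, values
within 1e-9 relative of an integer are snapped to it, so an exactly
invertible target is not pushed down a whole ton by float rounding.
Inversion refuses (raises) when β ≤ 0 or when the no-burning baseline α
already exceeds the target — there is then no defensible permissible
load, and silently returning 0 would hide a model failure.

A day *exceeds* when its emission total is strictly greater than X*
(operating exactly at the threshold is compliant). Burn-permit
screening projects a request's emission through the same E = A·B·C·EF
arithmetic and restricts when committed + projected mass would exceed
X* or when the dispersion forecast is adverse.

## 7. Synthetic scenario generator

The generator produces *statistically structured* inputs, not replicas
of real data. Scope: it emulates the features the pipeline is sensitive
to — seasonal fire intensity, land-cover composition, dual-sensor
detection with jitter, duplicates and misses, and a linear
emission–concentration coupling — and ships a ground-truth ledger
(true fires with areas, masses and classes; every detection linked to
its fire) so recovery can be measured.

- **Land cover:** a blocky mosaic (8 × 8 blocks of ~500 m cells) with
  group quotas apportioned by largest remainder, so realized fractions
  match the requested mix (default 62% forest / 31% agriculture / 7%
  other, the regional balance) within 2% by construction.
- **Ignitions:** an inhomogeneous Poisson process over burnable cells
  with piecewise-linear intensity: flat early season, linear ramp from
  mid-February to a mid-March peak (10× base rate), decay to a 2× tail
  by end of April. Default base rate 4 fires/day on the 2.0° × 1.6°
  domain.
- **Fire sizes:** lognormal footprint-scale areas (median 1.0 km²,
  σ_log = 0.35), chosen together with the detection probabilities so
  the detectable signal dominates observation noise at the default
  settings (see acceptance results).
- **Observation model:** independent detection by MODIS (p = 0.75,
  Gaussian jitter σ = 400 m, numeric confidence ~ N(90, 8) clipped)
  and VIIRS (p = 0.95, σ = 150 m, categorical confidence l/n/h with
  probabilities 0.06/0.50/0.44); with probability 0.1 an extra
  near-duplicate (σ ≤ 120 m, 1–6 h later, slightly lower confidence)
  is injected inside the fusion window, exercising deduplication.
  Overpass times fall in the 03:00–07:30 UTC daytime window.
- **PM2.5:** per station and day, Y = α_true + β_true·X_kg + ε with
  ε ~ N(0, 15²), α_true = 40.41, β_true = 6.31343e-6 per kg, 9 stations.
- **Reproducibility:** every random stream is a named child
  (CRC32-keyed `SeedSequence`) of the single scenario seed; identical
  seeds give byte-identical scenario files.

Under these defaults the full pipeline recovers the true daily emitted
mass with Pearson r ≈ 0.92–0.94 across seeds (the contract is r > 0.9),
while the *absolute* total is biased low (nominal footprints vs true
areas) — deliberately mirroring the operational system's behavior.

## 8. Numerical choices

- Exact conservation by construction: per-event cell weights are
  normalized to sum to 1, so gridding cannot leak mass.
- Deterministic tie-breaks everywhere ties can occur: dedup ordering
  (confidence, FRP, sensor, id), boundary points to the smallest
  subdistrict code, land-cover ties (1e-9 relative tolerance) to the
  higher emission product then the smaller class id.
- Threshold flooring with a 1e-9 relative integer snap (above).
- Sorting before any reduction that feeds output files, making tabular
  products byte-identical across re-runs of the same configuration.
- Problem sizes in tests and the acceptance script (sub-degree domains,
  121-day seasons, 200 regression replicates, 1,000-detection dedup
  oracle) are chosen so the whole suite runs in well under a minute on
  one CPU while still exercising every code path; they are this
  package's choices, not externally mandated values.

## 9. Limitations

- **Nominal footprints are not burned area.** A MODIS detection counts
  1 km² regardless of the true burn, so small fires are overestimated
  and large or repeated burns underestimated; daily *relative* dynamics
  are recovered well (r > 0.9 on synthetic truth) but absolute totals
  carry this structural bias.
- **Fuel parameters are class-level constants** — no seasonal fuel
  moisture, no within-class variability; B, C and EF uncertainties
  propagate multiplicatively into every total.
- **The regression is correlative**, not a transport model: it ignores
  meteorology, regional advection and secondary aerosol, so α and β
  are season- and region-specific and the threshold should be refit per
  season. The fitted-R² on synthetic seasons (~0.2–0.45) reflects the
  deliberately noisy coupling.
- **Cloud/overpass gaps** suppress detections in reality in ways the
  constant per-sensor detection probability only approximates.
- **The spherical projection** ignores ellipsoidal flattening;
  area errors (~0.1–0.3%) are negligible against footprint
  quantization but would matter for precision cadastral work.
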