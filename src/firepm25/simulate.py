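"""Synthetic fire-season scenario generator.

Emulates the statistical structure of the operational inputs so the whole
pipeline can be exercised end-to-end through its file interfaces: a blocky
500 m land-cover mosaic with the regional forest/agriculture balance, a
seasonal inhomogeneous Poisson ignition process peaking in mid-March,
dual-sensor (MODIS/VIIRS) detections with positional jitter, per-sensor
confidence draws and injected near-duplicate observations, a rectangular
administrative hierarchy, and station PM2.5 series responding linearly to
the daily emitted mass plus Gaussian noise.  A ground-truth ledger links
every detection back to its true fire for recovery tests.

All randomness flows from one seeded NumPy PCG64 generator, so a scenario
is fully reproducible from its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import box

from .detections import (
    DEFAULT_VIIRS_CONFIDENCE,
    FireDetection,
    RegionMask,
    Sensor,
)
from .errors import ArgumentError
from .landcover import FuelParameterTable, LandCoverGrid, NODATA, lc_group
from .proj import AlbersEqualArea
from .raster import GridGeoref

#: Concrete IGBP classes drawn within each land-use group, with weights.
GROUP_CLASS_POOLS = {
    "forest": ([2, 4, 5, 8, 9], [0.15, 0.35, 0.15, 0.2, 0.15]),
    "agriculture": ([12, 14], [0.8, 0.2]),
    "other": ([7, 10, 11, 13, 16, 17], [0.25, 0.3, 0.1, 0.15, 0.1, 0.1]),
}


@dataclass
class Scenario:
    """Configuration of one synthetic fire season."""

    seed: int = 0
    #: Study domain (west, south, east, north), degrees WGS84.
    bbox: tuple = (98.0, 18.0, 100.0, 19.6)
    #: Areal mix of land-use groups (fractions sum to 1); the default
    #: mirrors the regional balance of roughly 62% forest and 31%
    #: agriculture.
    landcover_mix: dict = field(
        default_factory=lambda: {"forest": 0.62, "agriculture": 0.31, "other": 0.07}
    )
    start: date = date(2024, 1, 1)
    end: date = date(2024, 4, 30)
    #: Early-season ignition intensity, true fires per day.
    base_rate: float = 4.0
    #: Mid-March peak intensity as a multiple of base_rate.
    peak_factor: float = 10.0
    #: Late-season floor as a multiple of base_rate.
    tail_factor: float = 2.0
    #: Per-sensor probability that a true fire is detected.
    p_detect: dict = field(default_factory=lambda: {"MODIS": 0.75, "VIIRS": 0.95})
    #: MODIS numeric confidence ~ Normal(mu, sigma), clipped to [0, 100].
    modis_conf_mu: float = 90.0
    modis_conf_sigma: float = 8.0
    #: VIIRS categorical confidence class probabilities.
    viirs_conf_probs: dict = field(
        default_factory=lambda: {"l": 0.06, "n": 0.5, "h": 0.44}
    )
    #: Positional jitter standard deviation per sensor, metres.
    jitter_m: dict = field(default_factory=lambda: {"MODIS": 400.0, "VIIRS": 150.0})
    #: Probability of injecting one extra near-duplicate per detection,
    #: within the 500 m / 24 h fusion rule's reach.
    duplicate_rate: float = 0.1
    #: True fire size distribution: lognormal of the footprint-scale burn.
    area_logmean: float = np.log(1.0)
    area_logsigma: float = 0.35
    #: Emission–concentration coupling (X in kg/day) and observation noise.
    alpha_true: float = 40.41
    beta_true_per_kg: float = 0.00000631343
    sigma_y: float = 15.0
    n_stations: int = 9
    #: Land-cover raster cell size (degrees, ~500 m) and mosaic block size
    #: in cells.
    lc_cell_deg: float = 0.005
    block_cells: int = 8

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def days(self) -> list[date]:
        return [self.start + timedelta(days=i) for i in range(self.n_days)]

    def rng(self, stream: str) -> np.random.Generator:
        """Independent child generator for one named random stream."""
        key = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def seasonal_intensity(scn: Scenario) -> np.ndarray:
    """Daily ignition intensity λ(t), fires/day, over the scenario window.

    Piecewise-linear season: flat early dry season, a ramp to the
    mid-March peak (``peak_factor`` times the base rate), then a decay to
    the late-April tail.
    """
    t = np.arange(scn.n_days, dtype=float)
    T = max(scn.n_days - 1, 1)
    ramp_start, peak_day = 0.37 * T, 0.61 * T  # mid-Feb, mid-Mar for Jan-Apr
    shape = np.ones_like(t)
    up = (t >= ramp_start) & (t <= peak_day)
    shape[up] = 1 + (scn.peak_factor - 1) * (t[up] - ramp_start) / (peak_day - ramp_start)
    down = t > peak_day
    shape[down] = scn.peak_factor + (scn.tail_factor - scn.peak_factor) * (
        t[down] - peak_day
    ) / (T - peak_day)
    return scn.base_rate * shape


def gen_landcover(scn: Scenario) -> LandCoverGrid:
    """Blocky random land-cover mosaic matching the group mix within 2%."""
    west, south, east, north = scn.bbox
    if east <= west or north <= south:
        raise ArgumentError("empty bounding box")
    if abs(sum(scn.landcover_mix.values()) - 1.0) > 1e-9:
        raise ArgumentError("land-cover mix fractions must sum to 1")
    ncols = int((east - west) / scn.lc_cell_deg) // scn.block_cells * scn.block_cells
    nrows = int((north - south) / scn.lc_cell_deg) // scn.block_cells * scn.block_cells
    nbx, nby = ncols // scn.block_cells, nrows // scn.block_cells
    nblocks = nbx * nby

    # largest-remainder apportionment gives exact group fractions at block
    # granularity, hence realized areal fractions within the 2% contract
    groups = list(scn.landcover_mix)
    quotas = np.array([scn.landcover_mix[g] * nblocks for g in groups])
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts))[: nblocks - counts.sum()]:
        counts[i] += 1

    rng = scn.rng("landcover")
    labels = np.repeat(np.arange(len(groups)), counts)
    rng.shuffle(labels)
    block_classes = np.empty(nblocks, dtype=np.uint8)
    for gi, g in enumerate(groups):
        pool, w = GROUP_CLASS_POOLS[g]
        sel = labels == gi
        block_classes[sel] = rng.choice(pool, size=sel.sum(), p=np.array(w) / sum(w))
    data = (
        block_classes.reshape(nby, nbx)
        .repeat(scn.block_cells, axis=0)
        .repeat(scn.block_cells, axis=1)
    )
    georef = GridGeoref(
        west=west, north=south + nrows * scn.lc_cell_deg,
        dx=scn.lc_cell_deg, dy=scn.lc_cell_deg, ncols=ncols, nrows=nrows,
    )
    return LandCoverGrid(data=data.astype(np.uint8), georef=georef, nodata=NODATA)


def gen_admin(scn: Scenario, n_prov=(4, 2), n_dist=(2, 2), n_sub=(2, 2)) -> RegionMask:
    """Rectangular administrative hierarchy tiling the domain.

    ``n_prov`` provinces (cols x rows), each split into ``n_dist``
    districts, each into ``n_sub`` subdistricts; codes are zero-padded
    hierarchical strings (province ``PP``, district ``PPDD``, subdistrict
    ``PPDDSS``).
    """
    west, south, east, north = scn.bbox
    feats = []
    pw = (east - west) / n_prov[0]
    ph = (north - south) / n_prov[1]
    p = 0
    for pi in range(n_prov[0]):
        for pj in range(n_prov[1]):
            p += 1
            pwest, psouth = west + pi * pw, south + pj * ph
            dw, dh = pw / n_dist[0], ph / n_dist[1]
            d = 0
            for di in range(n_dist[0]):
                for dj in range(n_dist[1]):
                    d += 1
                    dwest, dsouth = pwest + di * dw, psouth + dj * dh
                    sw, sh = dw / n_sub[0], dh / n_sub[1]
                    s = 0
                    for si in range(n_sub[0]):
                        for sj in range(n_sub[1]):
                            s += 1
                            geom = box(
                                dwest + si * sw, dsouth + sj * sh,
                                dwest + (si + 1) * sw, dsouth + (sj + 1) * sh,
                            )
                            feats.append(
                                (
                                    {
                                        "province": f"{p:02d}",
                                        "district": f"{p:02d}{d:02d}",
                                        "subdistrict": f"{p:02d}{d:02d}{s:02d}",
                                    },
                                    geom,
                                )
                            )
    return RegionMask(feats)


def _draw_confidence(rng, sensor: str, scn: Scenario) -> tuple[float, str]:
    """(normalized percent, raw token) for one detection."""
    if sensor == "MODIS":
        v = float(np.clip(rng.normal(scn.modis_conf_mu, scn.modis_conf_sigma), 0, 100))
        return v, f"{v:.0f}"
    cats = list(scn.viirs_conf_probs)
    probs = np.array([scn.viirs_conf_probs[c] for c in cats], dtype=float)
    tok = str(rng.choice(cats, p=probs / probs.sum()))
    return DEFAULT_VIIRS_CONFIDENCE[tok], tok


def gen_detections(
    scn: Scenario,
    grid: LandCoverGrid,
    table: FuelParameterTable | None = None,
    projection: AlbersEqualArea | None = None,
) -> tuple[list[FireDetection], pd.DataFrame, pd.DataFrame]:
    """Draw a season of true fires and their satellite observations.

    True fires are an inhomogeneous Poisson process over burnable cells
    with the seasonal intensity; each fire is observed independently by
    MODIS and/or VIIRS with positional jitter and per-sensor confidence
    draws, and near-duplicate observations are injected at the configured
    rate within the 500 m / 24 h fusion window.

    Returns (detections, fires ledger, observations ledger); the fires
    ledger carries the true burned area and true emitted mass (kg) per
    fire, the observations ledger maps each detection id to its fire.
    """
    table = table or FuelParameterTable.default()
    proj = projection or AlbersEqualArea()
    rng = scn.rng("fires")
    lam = seasonal_intensity(scn)
    g = grid.georef

    burn_rows, burn_cols = np.nonzero(
        np.isin(grid.data, [c for c in range(1, 18) if table.is_burnable(c)])
    )
    if burn_rows.size == 0:
        raise ArgumentError("no burnable land in scenario land cover")

    detections: list[FireDetection] = []
    fire_rows = []
    obs_rows = []
    fire_id = 0
    for di, day in enumerate(scn.days()):
        n_fires = rng.poisson(lam[di])
        for _ in range(n_fires):
            k = rng.integers(burn_rows.size)
            r, c = int(burn_rows[k]), int(burn_cols[k])
            lon = g.west + (c + rng.random()) * g.dx
            lat = g.north - (r + rng.random()) * g.dy
            lc = int(grid.data[r, c])
            area = float(rng.lognormal(scn.area_logmean, scn.area_logsigma))
            b, cc, ef = table.params(lc)
            true_kg = area * b * cc * ef * 1000.0  # tons -> kg
            # daytime overpass window, ~03:00-07:30 UTC (10:00-14:30 local)
            base_minutes = int(rng.integers(180, 450))
            n_obs = 0
            for sensor in ("MODIS", "VIIRS"):
                if rng.random() >= scn.p_detect[sensor]:
                    continue
                obs = _make_observation(
                    scn, rng, proj, fire_id, sensor, lon, lat, day,
                    base_minutes + int(rng.integers(-30, 30)), area,
                    det_id=f"SYN{len(detections):07d}",
                )
                detections.append(obs[0])
                obs_rows.append(obs[1])
                n_obs += 1
                if rng.random() < scn.duplicate_rate:
                    dup = _make_observation(
                        scn, rng, proj, fire_id, sensor, lon, lat, day,
                        base_minutes + int(rng.integers(60, 360)), area,
                        duplicate=True, det_id=f"SYN{len(detections):07d}",
                    )
                    detections.append(dup[0])
                    obs_rows.append(dup[1])
                    n_obs += 1
            fire_rows.append(
                {
                    "fire_id": fire_id,
                    "date": day.isoformat(),
                    "lon": lon,
                    "lat": lat,
                    "lc_class": lc,
                    "lc_group": lc_group(lc),
                    "true_area_km2": area,
                    "true_kg": true_kg,
                    "n_observations": n_obs,
                }
            )
            fire_id += 1
    fires = pd.DataFrame(fire_rows)
    obs = pd.DataFrame(obs_rows)
    return detections, fires, obs


def _make_observation(
    scn, rng, proj, fire_id, sensor, lon, lat, day, minutes, area,
    duplicate=False, det_id="SYN0000000",
):
    x, y = proj.forward(lon, lat)
    sigma = scn.jitter_m[sensor]
    if duplicate:
        # place inside the fusion radius so deduplication can remove it
        sigma = min(sigma, 120.0)
    ox, oy = rng.normal(0, sigma, size=2)
    olon, olat = proj.inverse(x + ox, y + oy)
    conf, raw = _draw_confidence(rng, sensor, scn)
    if duplicate:
        conf = max(0.0, conf - 5.0)
    minutes = int(np.clip(minutes, 0, 1439))
    ts = pd.Timestamp(day, tz="UTC") + pd.Timedelta(minutes=minutes)
    frp = float(max(0.5, rng.gamma(2.0, 8.0) * area))
    det = FireDetection(
        id=det_id,
        lat=float(olat),
        lon=float(olon),
        acq_time=ts,
        sensor=Sensor(sensor),
        confidence=conf,
        frp=frp,
        raw_confidence=raw,
    )
    return det, {
        "det_id": det_id,
        "fire_id": fire_id,
        "sensor": sensor,
        "is_duplicate": duplicate,
        "confidence": conf,
        "acq_time_utc": ts.isoformat(),
    }


def gen_pm25(scn: Scenario, daily_emissions_kg: pd.Series) -> pd.DataFrame:
    """Station PM2.5 (µg m⁻³) responding linearly to daily emissions.

    Per station s and day d: Y = α_true + β_true·X_d + ε, with
    ε ~ Normal(0, σ_y²) independent across stations and days.  Returns a
    date-indexed frame with one column per station.
    """
    rng = scn.rng("pm25")
    x = daily_emissions_kg.to_numpy(dtype=float)
    base = scn.alpha_true + scn.beta_true_per_kg * x
    noise = rng.normal(0.0, scn.sigma_y, size=(x.size, scn.n_stations))
    data = base[:, None] + noise
    return pd.DataFrame(
        data,
        index=daily_emissions_kg.index,
        columns=[f"station_{i + 1:02d}" for i in range(scn.n_stations)],
    )


# ---------------------------------------------------------------------------
# File interface: write the same formats the ingest pipeline reads.

_MODIS_COLUMNS = [
    "latitude", "longitude", "brightness", "scan", "track", "acq_date",
    "acq_time", "satellite", "instrument", "confidence", "version",
    "bright_t31", "frp", "daynight",
]
_VIIRS_COLUMNS = [
    "latitude", "longitude", "bright_ti4", "scan", "track", "acq_date",
    "acq_time", "satellite", "instrument", "confidence", "version",
    "bright_ti5", "frp", "daynight",
]


def detections_to_firms_csv(dets, outdir) -> dict[str, str]:
    """Write detections as MODIS/VIIRS FIRMS-dialect CSVs; returns paths."""
    import os

    paths = {}
    for sensor, cols in (("MODIS", _MODIS_COLUMNS), ("VIIRS", _VIIRS_COLUMNS)):
        rows = []
        for d in dets:
            if d.sensor.value != sensor:
                continue
            rows.append(
                {
                    "latitude": round(d.lat, 5),
                    "longitude": round(d.lon, 5),
                    cols[2]: 330.0,
                    "scan": 1.0,
                    "track": 1.0,
                    "acq_date": d.acq_time.strftime("%Y-%m-%d"),
                    "acq_time": d.acq_time.strftime("%H%M"),
                    "satellite": "Terra" if sensor == "MODIS" else "N",
                    "instrument": "MODIS" if sensor == "MODIS" else "VIIRS",
                    "confidence": d.raw_confidence,
                    "version": "6.1NRT" if sensor == "MODIS" else "2.0NRT",
                    cols[11]: 300.0,
                    "frp": round(d.frp, 2),
                    "daynight": "D",
                }
            )
        path = os.path.join(outdir, f"detections_{sensor.lower()}.csv")
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths[sensor] = path
    return paths


def write_scenario(scn: Scenario, outdir) -> dict[str, str]:
    """Materialize a full scenario through the pipeline's file formats.

    Writes the land-cover GeoTIFF, admin GeoJSON, per-sensor FIRMS-dialect
    detection CSVs, the fuel-parameter CSV, the station PM2.5 CSV and the
    ground-truth ledgers; returns a name → path mapping.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    table = FuelParameterTable.default()
    grid = gen_landcover(scn)
    mask = gen_admin(scn)
    dets, fires, obs = gen_detections(scn, grid, table)

    days = pd.DatetimeIndex([pd.Timestamp(d) for d in scn.days()])
    if len(fires):
        daily_kg = (
            fires.assign(date=pd.to_datetime(fires["date"]))
            .groupby("date")["true_kg"].sum()
            .reindex(days, fill_value=0.0)
        )
    else:
        daily_kg = pd.Series(0.0, index=days)
    pm25 = gen_pm25(scn, daily_kg)

    paths = {"landcover": os.path.join(outdir, "landcover.tif"),
             "admin": os.path.join(outdir, "admin.geojson"),
             "fuel": os.path.join(outdir, "fuel_parameters.csv"),
             "pm25": os.path.join(outdir, "stations_pm25.csv"),
             "fires_truth": os.path.join(outdir, "truth_fires.csv"),
             "obs_truth": os.path.join(outdir, "truth_observations.csv")}
    grid.to_geotiff(paths["landcover"])
    mask.to_geojson(paths["admin"])
    table.to_csv(paths["fuel"])
    pm25.rename_axis("date").to_csv(paths["pm25"], date_format="%Y-%m-%d")
    fires.to_csv(paths["fires_truth"], index=False)
    obs.to_csv(paths["obs_truth"], index=False)
    paths.update(detections_to_firms_csv(dets, outdir))
    return paths
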