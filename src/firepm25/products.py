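"""Output product writers: rasters, tables, reports and provenance.

One pipeline run materializes as daily GeoTIFF emission rasters, a single
NetCDF stack (time × lat × lon), per-event and summary CSV/JSON tables,
event polygons as GeoJSON, an analytics report (regression, threshold,
exceedance calendar) and a machine-readable provenance record that
suffices to re-run the products (configuration, input digests, package
version).  Tabular outputs are byte-identical for identical configuration
and seed.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping

from . import __version__
from .aggregate import summaries_to_frame
from .pipeline import PipelineResult, RunConfig
from .raster import write_geotiff


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def events_to_geojson(result: PipelineResult, path) -> None:
    feats = []
    for ev in result.events:
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "event_id": ev.event_id,
                    "date": ev.date.isoformat(),
                    "area_km2": ev.area_km2,
                    "n_members": len(ev.member_ids),
                    "frp_sum_mw": ev.frp_sum,
                    "lc_class": ev.lc_class,
                    "province": ev.province,
                },
                "geometry": mapping(ev.geometry_lonlat),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def records_to_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [r.event_id for r in result.records],
            "date": [r.date.isoformat() for r in result.records],
            "lc_class": [r.lc_class for r in result.records],
            "area_km2": [r.area_km2 for r in result.records],
            "pm25_tons": [r.pm25_tons for r in result.records],
            "frp_sum_mw": [r.frp_sum for r in result.records],
            "province": [r.province for r in result.records],
            "district": [r.district for r in result.records],
            "subdistrict": [r.subdistrict for r in result.records],
            "burnable": [r.burnable for r in result.records],
        }
    )


def grids_to_netcdf(result: PipelineResult, path) -> None:
    """Stack the daily emission grids into one NetCDF file (tons/cell/day)."""
    dates = sorted(result.grids)
    if not dates:
        raise ValueError("no daily grids to write")
    georef = result.grids[dates[0]].georef
    stack = np.stack([result.grids[d].data for d in dates])
    ds = xr.Dataset(
        {"pm25_tons": (("time", "lat", "lon"), stack)},
        coords={
            "time": pd.DatetimeIndex([pd.Timestamp(d) for d in dates]),
            "lat": georef.lat_centers(),
            "lon": georef.lon_centers(),
        },
        attrs={"description": "daily biomass-burning PM2.5 emissions, tons per cell"},
    )
    ds.to_netcdf(path, engine="scipy")


def analytics_report(result: PipelineResult) -> dict:
    rep: dict = {"n_events": len(result.events),
                 "total_pm25_tons": float(sum(r.pm25_tons for r in result.records))}
    if result.regression is not None:
        reg = result.regression
        rep["regression"] = {
            "alpha_ug_m3": reg.alpha,
            "beta_ug_m3_per_x": reg.beta,
            "x_unit": reg.x_unit.value,
            "r": reg.r,
            "r2": reg.r2,
            "p_slope": reg.p,
            "n_days": reg.n,
        }
    if result.threshold is not None:
        rep["emission_control_threshold"] = {
            "y_target_ug_m3": result.threshold.y_target,
            "x_star_tons_day": result.threshold.x_star,
        }
    if result.exceedance is not None:
        rep["exceedance"] = {
            "n_exceed": result.exceedance["n_exceed"],
            "n_days": result.exceedance["n_days"],
            "runs": result.exceedance["runs"],
        }
    if result.frp_daily_r is not None:
        rep["frp_emission_daily_r"] = result.frp_daily_r
    return rep


def write_products(
    result: PipelineResult,
    outdir,
    config: RunConfig | None = None,
    input_paths: dict | None = None,
) -> dict[str, object]:
    """Write the full product set; returns a name → path manifest."""
    os.makedirs(outdir, exist_ok=True)
    rasters = []
    for d in sorted(result.grids):
        g = result.grids[d]
        p = os.path.join(outdir, f"emissions_{d.isoformat()}.tif")
        write_geotiff(p, g.data.astype("float64"), g.georef)
        rasters.append(p)
    manifest: dict[str, object] = {"rasters": rasters}

    if result.grids:
        manifest["netcdf"] = os.path.join(outdir, "emissions_daily.nc")
        grids_to_netcdf(result, manifest["netcdf"])

    manifest["events_geojson"] = os.path.join(outdir, "fire_events.geojson")
    events_to_geojson(result, manifest["events_geojson"])

    manifest["events_csv"] = os.path.join(outdir, "emissions_by_event.csv")
    records_to_frame(result).to_csv(manifest["events_csv"], index=False)

    daily = pd.DataFrame(
        {"pm25_tons": result.daily.daily, "cumulative_tons": result.daily.cumulative}
    )
    manifest["daily_csv"] = os.path.join(outdir, "emissions_daily.csv")
    daily.rename_axis("date").to_csv(manifest["daily_csv"], date_format="%Y-%m-%d")

    for level, summaries in result.summaries.items():
        p = os.path.join(outdir, f"summary_{level}.csv")
        summaries_to_frame(summaries).to_csv(p, index=False)
        manifest[f"summary_{level}"] = p
    manifest["summary_json"] = os.path.join(outdir, "summary.json")
    with open(manifest["summary_json"], "w") as fh:
        json.dump(
            {
                level: summaries_to_frame(s).to_dict(orient="records")
                for level, s in result.summaries.items()
            },
            fh,
            indent=1,
        )

    manifest["analytics_json"] = os.path.join(outdir, "analytics.json")
    with open(manifest["analytics_json"], "w") as fh:
        json.dump(analytics_report(result), fh, indent=1)

    if result.exceedance is not None:
        cal = pd.DataFrame(
            {
                "pm25_tons": result.daily.daily,
                "flag": result.exceedance["flags"],
            }
        )
        manifest["exceedance_csv"] = os.path.join(outdir, "exceedance_calendar.csv")
        cal.rename_axis("date").to_csv(
            manifest["exceedance_csv"], date_format="%Y-%m-%d"
        )

    if result.qc_log:
        manifest["qc_log"] = os.path.join(outdir, "qc_log.json")
        with open(manifest["qc_log"], "w") as fh:
            json.dump(result.qc_log, fh, indent=1)

    prov = {
        "package": "firepm25",
        "version": __version__,
        "config": (config or RunConfig()).to_dict(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (input_paths or {}).items()
            if p is not None and os.path.exists(str(p))
        },
    }
    prov["config_sha256"] = hashlib.sha256(
        json.dumps(prov["config"], sort_keys=True).encode()
    ).hexdigest()
    manifest["provenance"] = os.path.join(outdir, "provenance.json")
    with open(manifest["provenance"], "w") as fh:
        json.dump(prov, fh, indent=1)
    return manifest
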