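"""Multiscale aggregation of emission records.

Emissions are rolled up the administrative hierarchy
(event → subdistrict → district → province → region) and along time
(daily → cumulative → calendar month).  Summaries include emission
density (tons km⁻²), provincial shares of the regional total, and
forest/agriculture/other land-use splits with per-group intensities.
Mass is conserved at every level: children always sum to their parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.ops import transform, unary_union

from .detections import RegionMask
from .emission import EmissionRecord
from .errors import ArgumentError
from .landcover import lc_group
from .proj import AlbersEqualArea

LEVELS = ("subdistrict", "district", "province", "region")


@dataclass
class AdminSummary:
    """Emission totals for one administrative unit over a period."""

    code: str
    level: str
    period: str
    tons: float
    area_km2: float | None = None
    density_t_km2: float | None = None
    share_pct: float | None = None
    lc_tons: dict = field(default_factory=dict)


class DailySeries:
    """Daily emission totals with a cumulative companion series."""

    def __init__(self, daily: pd.Series):
        daily = daily.sort_index()
        daily.index = pd.DatetimeIndex(daily.index)
        # fill calendar gaps with zero-emission days
        if len(daily) > 1:
            full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
            daily = daily.reindex(full, fill_value=0.0)
        self.daily = daily

    @classmethod
    def from_records(cls, records: Sequence[EmissionRecord], window=None) -> "DailySeries":
        if records:
            s = (
                pd.DataFrame(
                    {"date": [pd.Timestamp(r.date) for r in records],
                     "tons": [r.pm25_tons for r in records]}
                )
                .groupby("date")["tons"]
                .sum()
            )
        else:
            s = pd.Series(dtype=float)
        if window is not None:
            full = pd.date_range(window[0], window[1], freq="D")
            s = s.reindex(full, fill_value=0.0)
        return cls(s)

    @property
    def cumulative(self) -> pd.Series:
        return self.daily.cumsum()

    def monthly(self) -> pd.Series:
        """Calendar-month totals (local time)."""
        return self.daily.resample("MS").sum()

    def monthly_mean(self) -> float:
        """Mean of the calendar-month totals over the window."""
        m = self.monthly()
        return float(m.mean()) if len(m) else float("nan")

    def total(self) -> float:
        return float(self.daily.sum())


def density(tons: float, area_km2: float) -> float:
    """Emission density in tons km⁻² (summaries report it to 2 d.p.)."""
    if area_km2 <= 0:
        raise ArgumentError("area_km2 must be > 0")
    return tons / area_km2


def _unit_code(rec: EmissionRecord, level: str) -> str:
    code = {
        "subdistrict": rec.subdistrict,
        "district": rec.district,
        "province": rec.province,
        "region": "region",
    }.get(level)
    if level not in LEVELS:
        raise ArgumentError(f"unknown admin level {level!r}")
    if code is None:
        raise ArgumentError(f"record {rec.event_id} lacks a {level} code")
    return code


def admin_areas(
    mask: RegionMask, level: str, projection: AlbersEqualArea | None = None
) -> dict[str, float]:
    """Land area (km², equal-area frame) of each unit at ``level``."""
    proj = projection or AlbersEqualArea()

    def fwd(x, y):
        return proj.forward(np.asarray(x), np.asarray(y))

    groups: dict[str, list] = {}
    for (p, d, s), geom in mask.records:
        key = {"subdistrict": s, "district": d, "province": p, "region": "region"}[level]
        groups.setdefault(key, []).append(geom)
    return {
        k: transform(fwd, unary_union(gs)).area / 1e6 for k, gs in groups.items()
    }


def aggregate_admin(
    records: Sequence[EmissionRecord],
    mask: RegionMask,
    level: str,
    period: str = "all",
    projection: AlbersEqualArea | None = None,
) -> list[AdminSummary]:
    """Sum emissions per administrative unit with densities and shares.

    Every record's code must exist in the mask; shares are percentages of
    the regional total and sum to 100 over the level (up to rounding).
    """
    if level not in LEVELS:
        raise ArgumentError(f"unknown admin level {level!r}")
    areas = admin_areas(mask, level, projection)
    totals: dict[str, float] = {k: 0.0 for k in areas}
    lc_totals: dict[str, dict[str, float]] = {k: {} for k in areas}
    for rec in records:
        code = _unit_code(rec, level)
        if code not in totals:
            raise ArgumentError(f"record {rec.event_id}: unknown {level} code {code!r}")
        totals[code] += rec.pm25_tons
        g = lc_group(rec.lc_class)
        lc_totals[code][g] = lc_totals[code].get(g, 0.0) + rec.pm25_tons
    region_total = sum(totals.values())
    out = []
    for code in sorted(totals):
        tons = totals[code]
        area = areas[code]
        out.append(
            AdminSummary(
                code=code,
                level=level,
                period=period,
                tons=tons,
                area_km2=area,
                density_t_km2=density(tons, area) if area > 0 else None,
                share_pct=(100.0 * tons / region_total) if region_total > 0 else None,
                lc_tons=lc_totals[code],
            )
        )
    return out


def series(
    records: Sequence[EmissionRecord], window=None
) -> tuple[DailySeries, pd.Series, float]:
    """Daily series, calendar-month totals and their mean."""
    ds = DailySeries.from_records(records, window=window)
    monthly = ds.monthly()
    return ds, monthly, ds.monthly_mean()


def lc_split(
    records: Sequence[EmissionRecord],
    group_areas: Mapping[str, Mapping[str, float]],
    level: str = "province",
) -> pd.DataFrame:
    """Forest/agriculture/other totals and intensities per admin unit.

    ``group_areas`` maps admin code → land-use group → land area (km²).
    Returns a frame indexed by (code, group) with columns ``tons`` and
    ``intensity_t_km2``; a record whose unit lacks a group area raises.
    """
    rows: dict[tuple[str, str], float] = {}
    for rec in records:
        code = _unit_code(rec, level)
        g = lc_group(rec.lc_class)
        rows[(code, g)] = rows.get((code, g), 0.0) + rec.pm25_tons
    out = []
    for (code, g), tons in sorted(rows.items()):
        if code not in group_areas or g not in group_areas[code]:
            raise ArgumentError(f"missing {g!r} area for admin unit {code!r}")
        area = group_areas[code][g]
        out.append(
            {"code": code, "group": g, "tons": tons,
             "area_km2": area, "intensity_t_km2": density(tons, area)}
        )
    return pd.DataFrame(out).set_index(["code", "group"]) if out else pd.DataFrame(
        columns=["tons", "area_km2", "intensity_t_km2"]
    )


def summaries_to_frame(summaries: Sequence[AdminSummary]) -> pd.DataFrame:
    """Tabular view with the conventional rounding (density 2 d.p., share 1 d.p.)."""
    return pd.DataFrame(
        {
            "code": [s.code for s in summaries],
            "level": [s.level for s in summaries],
            "period": [s.period for s in summaries],
            "pm25_tons": [s.tons for s in summaries],
            "area_km2": [s.area_km2 for s in summaries],
            "density_t_km2": [
                None if s.density_t_km2 is None else round(s.density_t_km2, 2)
                for s in summaries
            ],
            "share_pct": [
                None if s.share_pct is None else round(s.share_pct, 1)
                for s in summaries
            ],
        }
    )
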