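"""Effective burned-area geometry.

Each cleaned hotspot is expanded to its sensor-specific footprint — a
square of 1 km² for MODIS and 0.140625 km² (375 m x 375 m) for VIIRS —
centred on the detection in an equal-area projected frame.  Footprints
from the same local civil day are merged into contiguous fire events by
connected-component clustering on spatial overlap (optionally within a gap
tolerance), and the effective burned area A of each event is the area of
the unbuffered union of its member footprints, so overlapping footprints
are never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import transform, unary_union
from shapely.strtree import STRtree

from .detections import FireDetection, Sensor
from .errors import ArgumentError, GeometryError
from .proj import AlbersEqualArea

#: Footprint side length in metres by sensor.
FOOTPRINT_SIDE_M = {Sensor.MODIS: 1000.0, Sensor.VIIRS: 375.0}

#: Local civil time offset of the study region (Indochina Time, UTC+7).
LOCAL_UTC_OFFSET_H = 7


@dataclass(frozen=True)
class FootprintPolygon:
    """Square sensor footprint of one detection in the projected frame."""

    detection_id: str
    geometry: object  # shapely Polygon, metres
    nominal_area_km2: float
    detection: FireDetection


@dataclass
class FireEvent:
    """A contiguous burned patch for one local civil day.

    ``geometry`` is the union of member footprints in the projected
    equal-area frame; ``area_km2`` is its planar area — the effective
    burned area A that drives the emission computation.
    """

    event_id: str
    geometry: object  # shapely (Multi)Polygon, metres
    area_km2: float
    date: object  # datetime.date, local civil date
    member_ids: list[str]
    frp_sum: float
    lc_class: int | None = None
    province: str | None = None
    district: str | None = None
    subdistrict: str | None = None
    geometry_lonlat: object | None = None
    rep_lon: float | None = None
    rep_lat: float | None = None


def footprint(
    det: FireDetection, projection: AlbersEqualArea | None = None
) -> FootprintPolygon:
    """Axis-aligned square footprint centred on the detection."""
    side = FOOTPRINT_SIDE_M.get(Sensor(det.sensor))
    if side is None:
        raise ArgumentError(f"unknown sensor {det.sensor!r}")
    proj = projection or AlbersEqualArea()
    x, y = proj.forward(det.lon, det.lat)
    half = side / 2.0
    geom = box(x - half, y - half, x + half, y + half)
    return FootprintPolygon(
        detection_id=det.id,
        geometry=geom,
        nominal_area_km2=(side / 1000.0) ** 2,
        detection=det,
    )


def cluster(
    footprints: list[FootprintPolygon],
    day,
    gap_tol_m: float = 0.0,
    projection: AlbersEqualArea | None = None,
) -> list[FireEvent]:
    """Merge one day's footprints into contiguous fire events.

    Two footprints belong to the same event when they intersect after each
    is buffered by ``gap_tol_m / 2`` (with the default tolerance of 0,
    only overlapping or touching footprints merge).  Event geometry is the
    unbuffered union of member footprints, so the result is independent of
    input order and never double-counts overlap.
    """
    if gap_tol_m < 0:
        raise ArgumentError("gap_tol_m must be >= 0")
    if not footprints:
        return []
    proj = projection or AlbersEqualArea()
    geoms = [fp.geometry for fp in footprints]
    probe = geoms if gap_tol_m == 0 else [g.buffer(gap_tol_m / 2.0) for g in geoms]

    parent = list(range(len(footprints)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = STRtree(probe)
    for i, g in enumerate(probe):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(len(footprints)):
        groups.setdefault(find(i), []).append(i)

    events = []
    # deterministic event ids: ordered by smallest member detection id
    ordered = sorted(groups.values(), key=lambda idx: min(footprints[i].detection_id for i in idx))
    for k, idx in enumerate(ordered):
        members = [footprints[i] for i in idx]
        geom = unary_union([m.geometry for m in members])
        ev = FireEvent(
            event_id=f"{day.isoformat()}-{k:05d}",
            geometry=geom,
            area_km2=geom.area / 1e6,
            date=day,
            member_ids=sorted(m.detection_id for m in members),
            frp_sum=float(sum(m.detection.frp for m in members)),
        )
        _finalize_geometry(ev, proj)
        events.append(ev)
    return events


def _finalize_geometry(event: FireEvent, proj: AlbersEqualArea) -> None:
    """Attach geographic geometry and a representative point."""

    def inv(x, y):
        return proj.inverse(np.asarray(x), np.asarray(y))

    event.geometry_lonlat = transform(inv, event.geometry)
    rp = event.geometry.centroid
    if not event.geometry.covers(rp):
        rp = event.geometry.representative_point()
    lon, lat = proj.inverse(rp.x, rp.y)
    event.rep_lon, event.rep_lat = float(lon), float(lat)


def event_area(event: FireEvent) -> float:
    """Effective burned area A of an event, km² in the equal-area frame."""
    if event.geometry is None or event.geometry.is_empty or not event.geometry.is_valid:
        raise GeometryError(f"event {event.event_id} has invalid geometry")
    return event.geometry.area / 1e6


def local_day(ts: pd.Timestamp, utc_offset_h: int = LOCAL_UTC_OFFSET_H):
    """Local civil date of a UTC timestamp (study region is UTC+7)."""
    return (ts + pd.Timedelta(hours=utc_offset_h)).date()


def build_daily_events(
    dets: list[FireDetection],
    gap_tol_m: float = 0.0,
    projection: AlbersEqualArea | None = None,
    utc_offset_h: int = LOCAL_UTC_OFFSET_H,
) -> list[FireEvent]:
    """Footprint + per-local-day clustering over a detection set."""
    proj = projection or AlbersEqualArea()
    by_day: dict[object, list[FootprintPolygon]] = {}
    for d in dets:
        by_day.setdefault(local_day(d.acq_time, utc_offset_h), []).append(
            footprint(d, proj)
        )
    events: list[FireEvent] = []
    for day in sorted(by_day):
        events.extend(cluster(by_day[day], day, gap_tol_m, proj))
    return events
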