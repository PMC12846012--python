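"""Active-fire detection ingest and quality control.

Parses FIRMS-style hotspot tables (MODIS MCD14DL and VIIRS VNP14IMGTDL CSV
dialects), normalizes detection confidence across sensors, applies the
confidence filter, removes cross-sensor duplicates within a spatial radius
and time window, and clips detections to the administrative study region.

The QC defaults follow the operational configuration for Upper Northern
Thailand: detections with confidence below 80% are discarded, and
detections within 500 m and 24 h of a higher-confidence record are treated
as duplicate observations of the same fire.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, shape, mapping
from shapely.strtree import STRtree

from .errors import ArgumentError, GeometryError, ParseError
from .proj import AlbersEqualArea, haversine_m


class Sensor(str, enum.Enum):
    """Satellite instrument that produced a detection."""

    MODIS = "MODIS"
    VIIRS = "VIIRS"


#: Default mapping of the VIIRS near-real-time categorical confidence
#: classes (low / nominal / high) onto percentages.  "Nominal" maps to 80
#: so that routine agricultural detections survive the default >=80 filter;
#: a literal numeric filter would discard nearly every VIIRS detection.
DEFAULT_VIIRS_CONFIDENCE: dict[str, float] = {"l": 30.0, "n": 80.0, "h": 100.0}

#: Greedy duplicate-suppression prefers VIIRS over MODIS at equal
#: confidence and FRP (the smaller footprint localizes the fire better).
_SENSOR_PRIORITY = {Sensor.VIIRS: 0, Sensor.MODIS: 1}


@dataclass(frozen=True)
class FireDetection:
    """One satellite hotspot record after confidence normalization."""

    id: str
    lat: float
    lon: float
    acq_time: pd.Timestamp
    sensor: Sensor
    confidence: float
    frp: float
    raw_confidence: str = ""
    province: str | None = None
    district: str | None = None
    subdistrict: str | None = None

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ArgumentError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ArgumentError(f"longitude {self.lon} outside [-180, 180]")
        if self.frp < 0:
            raise ArgumentError(f"FRP {self.frp} must be >= 0")
        if not 0.0 <= self.confidence <= 100.0:
            raise ArgumentError(f"confidence {self.confidence} outside [0, 100]")


@dataclass
class RowError:
    """A malformed input row, reported rather than silently dropped."""

    row: int
    message: str


def normalize_confidence(
    sensor: Sensor,
    raw,
    viirs_mapping: Mapping[str, float] | None = None,
) -> float:
    """Express detection confidence as a percentage in [0, 100].

    MODIS confidence is already a 0-100 number and passes through. VIIRS
    near-real-time confidence is categorical (``l``/``n``/``h``) and is
    mapped through ``viirs_mapping`` (default
    :data:`DEFAULT_VIIRS_CONFIDENCE`); numeric VIIRS values (as in the
    standard-product dialect) pass through unchanged.
    """
    sensor = Sensor(sensor)
    if sensor is Sensor.VIIRS:
        token = str(raw).strip().lower()
        table = DEFAULT_VIIRS_CONFIDENCE if viirs_mapping is None else viirs_mapping
        if token in table:
            return float(table[token])
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"unknown confidence token {raw!r} for sensor {sensor.value}")
    if not 0.0 <= value <= 100.0:
        raise ParseError(f"confidence {value} outside [0, 100]")
    return value


_MANDATORY_COLUMNS = ("latitude", "longitude", "acq_date", "acq_time", "confidence", "frp")


def _parse_acq_timestamp(date_str: str, time_val) -> pd.Timestamp:
    """Combine FIRMS acq_date + acq_time (HHMM integer or HH:MM) into UTC."""
    token = str(time_val).strip().replace(":", "")
    if not token.isdigit() or len(token) > 4:
        raise ValueError(f"unparseable acq_time {time_val!r}")
    token = token.zfill(4)
    hh, mm = int(token[:2]), int(token[2:])
    if hh > 23 or mm > 59:
        raise ValueError(f"acq_time {time_val!r} out of range")
    ts = pd.Timestamp(f"{date_str} {hh:02d}:{mm:02d}", tz="UTC")
    if pd.isna(ts):
        raise ValueError(f"unparseable acq_date {date_str!r}")
    return ts


def parse_firms(
    source,
    dialect: Sensor | str,
    viirs_mapping: Mapping[str, float] | None = None,
) -> tuple[list[FireDetection], list[RowError]]:
    """Parse a FIRMS-dialect CSV into detections plus row-level errors.

    ``source`` may be a path or a file-like object. Raises
    :class:`ParseError` if a mandatory column is absent; malformed rows are
    returned in the error list, never silently dropped.
    """
    sensor = Sensor(dialect)
    try:
        table = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except Exception as exc:  # malformed CSV as a whole
        raise ParseError(f"cannot read detection table: {exc}") from exc
    table.columns = [c.strip().lower() for c in table.columns]
    for col in _MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"missing mandatory column {col!r} for {sensor.value} dialect")

    detections: list[FireDetection] = []
    errors: list[RowError] = []
    for i, row in enumerate(table.itertuples(index=False)):
        rec = dict(zip(table.columns, row))
        try:
            lat = float(rec["latitude"])
            lon = float(rec["longitude"])
            acq = _parse_acq_timestamp(rec["acq_date"], rec["acq_time"])
            frp = float(rec["frp"]) if rec["frp"] not in (None, "") else 0.0
            conf = normalize_confidence(sensor, rec["confidence"], viirs_mapping)
            det = FireDetection(
                id=f"{sensor.value[0]}{i:06d}",
                lat=lat,
                lon=lon,
                acq_time=acq,
                sensor=sensor,
                confidence=conf,
                frp=frp,
                raw_confidence=str(rec["confidence"]),
            )
        except (ValueError, TypeError, ArgumentError, ParseError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
            continue
        detections.append(det)
    return detections, errors


def filter_confidence(
    dets: Sequence[FireDetection], min_conf: float = 80.0
) -> list[FireDetection]:
    """Retain detections with confidence >= ``min_conf``, preserving order."""
    return [d for d in dets if d.confidence >= min_conf]


def deduplicate(
    dets: Sequence[FireDetection],
    radius_m: float = 500.0,
    window_h: float = 24.0,
    projection: AlbersEqualArea | None = None,
) -> list[FireDetection]:
    """Suppress cross-sensor duplicate observations of the same fire.

    Greedy suppression: detections are ranked by descending
    (confidence, FRP, sensor priority VIIRS > MODIS, id); each survivor
    removes every lower-ranked detection within ``radius_m`` great-circle
    metres and ``window_h`` hours (absolute time difference).  The procedure
    is deterministic and idempotent, and every survivor has confidence at
    least that of each record it suppressed.
    """
    if radius_m < 0 or window_h < 0:
        raise ArgumentError("radius_m and window_h must be >= 0")
    if not dets:
        return []
    proj = projection or AlbersEqualArea()
    order = sorted(
        range(len(dets)),
        key=lambda i: (
            -dets[i].confidence,
            -dets[i].frp,
            _SENSOR_PRIORITY[dets[i].sensor],
            dets[i].id,
        ),
    )
    lons = np.array([d.lon for d in dets])
    lats = np.array([d.lat for d in dets])
    x, y = proj.forward(lons, lats)
    tree = cKDTree(np.column_stack([x, y]))
    times = np.array([d.acq_time.value for d in dets], dtype="int64")  # ns
    window_ns = window_h * 3.6e12

    rank = np.empty(len(dets), dtype=int)
    rank[order] = np.arange(len(dets))
    suppressed = np.zeros(len(dets), dtype=bool)
    survivors: list[int] = []
    # KD-tree query radius is padded: projected distances can differ from
    # great-circle by a small factor; the exact haversine test decides.
    pad = radius_m * 1.05 + 10.0
    for i in order:
        if suppressed[i]:
            continue
        survivors.append(i)
        for j in tree.query_ball_point([x[i], y[i]], r=pad):
            if j == i or suppressed[j] or rank[j] < rank[i]:
                continue
            if abs(times[j] - times[i]) > window_ns:
                continue
            if haversine_m(lons[i], lats[i], lons[j], lats[j]) <= radius_m:
                suppressed[j] = True
    survivors_set = set(survivors)
    return [d for k, d in enumerate(dets) if k in survivors_set]


class RegionMask:
    """Administrative region polygons (WGS84) at subdistrict granularity.

    Each polygon carries ``province``, ``district`` and ``subdistrict``
    codes; district and province geometries are implied by code prefixes.
    """

    def __init__(self, features: Iterable[tuple[dict, object]]):
        """``features``: iterable of (properties, shapely geometry)."""
        self.records = []
        seen = set()
        for props, geom in features:
            if not geom.is_valid:
                raise GeometryError(
                    f"invalid polygon for subdistrict {props.get('subdistrict')!r}"
                )
            codes = (
                str(props["province"]),
                str(props["district"]),
                str(props["subdistrict"]),
            )
            if codes[2] in seen:
                raise GeometryError(f"duplicate subdistrict code {codes[2]!r}")
            seen.add(codes[2])
            self.records.append((codes, geom))
        # sort so that boundary ties resolve to the smallest code
        self.records.sort(key=lambda r: r[0])
        self._tree = STRtree([g for _, g in self.records])

    @classmethod
    def from_geojson(cls, source) -> "RegionMask":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        feats = [
            (f["properties"], shape(f["geometry"])) for f in doc["features"]
        ]
        return cls(feats)

    def to_geojson(self, path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {
                    "province": p, "district": d, "subdistrict": s,
                },
                "geometry": mapping(geom),
            }
            for (p, d, s), geom in self.records
        ]
        doc = {"type": "FeatureCollection", "features": feats}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    def locate(self, lon: float, lat: float) -> tuple[str, str, str] | None:
        """Codes of the polygon covering a point, or None if outside.

        A point on a shared boundary is assigned to the polygon with the
        lexicographically smallest subdistrict code.
        """
        pt = Point(lon, lat)
        hits = [
            self.records[k][0]
            for k in self._tree.query(pt, predicate="covered_by")
        ]
        return min(hits, key=lambda c: c[2]) if hits else None

    @property
    def union(self):
        from shapely.ops import unary_union

        return unary_union([g for _, g in self.records])


def clip_to_region(
    dets: Sequence[FireDetection], mask: RegionMask
) -> list[FireDetection]:
    """Keep detections inside the region, annotated with admin codes."""
    out = []
    for d in dets:
        codes = mask.locate(d.lon, d.lat)
        if codes is None:
            continue
        out.append(
            dataclasses.replace(
                d, province=codes[0], district=codes[1], subdistrict=codes[2]
            )
        )
    return out


def detections_to_frame(dets: Sequence[FireDetection]) -> pd.DataFrame:
    """Tabular view of detections (one row each), ISO-8601 UTC times."""
    return pd.DataFrame(
        {
            "id": [d.id for d in dets],
            "latitude": [d.lat for d in dets],
            "longitude": [d.lon for d in dets],
            "acq_time_utc": [d.acq_time.isoformat() for d in dets],
            "sensor": [d.sensor.value for d in dets],
            "confidence_pct": [d.confidence for d in dets],
            "frp_mw": [d.frp for d in dets],
            "province": [d.province for d in dets],
            "district": [d.district for d in dets],
            "subdistrict": [d.subdistrict for d in dets],
        }
    )


def detections_to_geojson(dets: Sequence[FireDetection], path) -> None:
    feats = []
    for d in dets:
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "id": d.id,
                    "acq_time_utc": d.acq_time.isoformat(),
                    "sensor": d.sensor.value,
                    "confidence_pct": d.confidence,
                    "frp_mw": d.frp,
                    "province": d.province,
                },
                "geometry": {"type": "Point", "coordinates": [d.lon, d.lat]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
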