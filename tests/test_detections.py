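"""Ingest QC: parsing, confidence normalization, filtering, deduplication
and region clipping."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon, box

from firepm25.detections import (
    RegionMask,
    Sensor,
    clip_to_region,
    deduplicate,
    filter_confidence,
    normalize_confidence,
    parse_firms,
)
from firepm25.errors import ArgumentError, GeometryError, ParseError
from firepm25.proj import haversine_m

from conftest import make_detection

MODIS_HEADER = (
    "latitude,longitude,brightness,scan,track,acq_date,acq_time,satellite,"
    "instrument,confidence,version,bright_t31,frp,daynight\n"
)
VIIRS_HEADER = (
    "latitude,longitude,bright_ti4,scan,track,acq_date,acq_time,satellite,"
    "instrument,confidence,version,bright_ti5,frp,daynight\n"
)


class TestParsing:
    def test_modis_row_maps_directly(self):
        src = io.StringIO(
            MODIS_HEADER
            + "19.0,99.0,330.1,1.0,1.0,2024-03-13,0635,Terra,MODIS,92,6.1NRT,300.0,25.4,D\n"
        )
        dets, errors = parse_firms(src, Sensor.MODIS)
        assert errors == []
        (d,) = dets
        assert (d.lat, d.lon) == (19.0, 99.0)
        assert d.acq_time == pd.Timestamp("2024-03-13T06:35:00Z")
        assert d.sensor is Sensor.MODIS
        assert d.confidence == 92.0
        assert d.frp == 25.4

    def test_viirs_categorical_confidence_is_mapped(self):
        src = io.StringIO(
            VIIRS_HEADER
            + "19.0,99.0,330.1,0.4,0.4,2024-03-13,0635,N,VIIRS,h,2.0NRT,290.0,5.0,D\n"
        )
        dets, errors = parse_firms(src, Sensor.VIIRS)
        assert errors == []
        assert dets[0].confidence == 100.0
        assert dets[0].raw_confidence == "h"

    def test_header_only_file_yields_empty_list_no_errors(self):
        dets, errors = parse_firms(io.StringIO(MODIS_HEADER), Sensor.MODIS)
        assert dets == [] and errors == []

    def test_missing_column_is_a_structured_error(self):
        src = io.StringIO("latitude,longitude,acq_date\n19.0,99.0,2024-03-13\n")
        with pytest.raises(ParseError, match="acq_time"):
            parse_firms(src, Sensor.MODIS)

    @pytest.mark.parametrize(
        "bad_row",
        [
            "abc,99.0,330,1,1,2024-03-13,0635,T,MODIS,92,6.1,300,25.4,D",  # coord
            "19.0,99.0,330,1,1,2024-03-13,9999,T,MODIS,92,6.1,300,25.4,D",  # time
            "19.0,99.0,330,1,1,2024-03-13,0635,T,MODIS,150,6.1,300,25.4,D",  # conf
        ],
    )
    def test_malformed_rows_are_reported_not_dropped(self, bad_row):
        good = "19.5,99.5,330,1,1,2024-03-13,0635,T,MODIS,92,6.1,300,25.4,D\n"
        src = io.StringIO(MODIS_HEADER + bad_row + "\n" + good)
        dets, errors = parse_firms(src, Sensor.MODIS)
        assert len(dets) == 1
        assert len(errors) == 1 and errors[0].row == 0


class TestNormalizeConfidence:
    @pytest.mark.parametrize(
        "sensor,raw,expected",
        [
            (Sensor.MODIS, 85, 85.0),
            (Sensor.VIIRS, "h", 100.0),
            (Sensor.VIIRS, "n", 80.0),
            (Sensor.VIIRS, "l", 30.0),
            (Sensor.VIIRS, "42", 42.0),  # standard-product numeric dialect
        ],
    )
    def test_mapping(self, sensor, raw, expected):
        assert normalize_confidence(sensor, raw) == expected

    def test_unknown_token_names_the_value(self):
        with pytest.raises(ParseError, match="xx"):
            normalize_confidence(Sensor.VIIRS, "xx")

    def test_custom_mapping_overrides_default(self):
        assert normalize_confidence(Sensor.VIIRS, "n", {"n": 55.0}) == 55.0


class TestFilterConfidence:
    def test_boundary_at_80_is_retained(self):
        dets = [make_detection(f"d{i}", confidence=c) for i, c in enumerate([79, 80, 95])]
        kept = filter_confidence(dets)
        assert [d.confidence for d in kept] == [80, 95]

    def test_empty_input(self):
        assert filter_confidence([]) == []

    @given(
        confs=st.lists(st.floats(0, 100), min_size=0, max_size=30),
        t1=st.floats(0, 100),
        t2=st.floats(0, 100),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_raising_threshold_never_increases_count(self, confs, t1, t2):
        dets = [make_detection(f"d{i}", confidence=c) for i, c in enumerate(confs)]
        lo, hi = sorted([t1, t2])
        assert len(filter_confidence(dets, hi)) <= len(filter_confidence(dets, lo))


def brute_force_dedup(dets, radius_m=500.0, window_h=24.0):
    """Independent O(n²) greedy-suppression oracle using pure haversine."""
    order = sorted(
        range(len(dets)),
        key=lambda i: (
            -dets[i].confidence,
            -dets[i].frp,
            0 if dets[i].sensor is Sensor.VIIRS else 1,
            dets[i].id,
        ),
    )
    alive = [True] * len(dets)
    survivors = []
    for pos, i in enumerate(order):
        if not alive[i]:
            continue
        survivors.append(i)
        for j in order[pos + 1:]:
            if not alive[j]:
                continue
            dt_h = abs((dets[i].acq_time - dets[j].acq_time).total_seconds()) / 3600
            if dt_h > window_h:
                continue
            if haversine_m(dets[i].lon, dets[i].lat, dets[j].lon, dets[j].lat) <= radius_m:
                alive[j] = False
    keep = set(survivors)
    return [d for k, d in enumerate(dets) if k in keep]


def random_detections(n, seed, spread_deg=0.02):
    rng = np.random.default_rng(seed)
    sensors = [Sensor.MODIS, Sensor.VIIRS]
    return [
        make_detection(
            f"r{i:04d}",
            lat=float(19.0 + rng.normal(0, spread_deg)),
            lon=float(99.0 + rng.normal(0, spread_deg)),
            when=pd.Timestamp("2024-03-01T00:00Z") + pd.Timedelta(hours=float(rng.uniform(0, 72))),
            sensor=sensors[int(rng.integers(2))],
            confidence=float(rng.uniform(50, 100)),
            frp=float(rng.uniform(0, 50)),
        )
        for i in range(n)
    ]


class TestDeduplicate:
    def test_close_pair_keeps_highest_confidence(self, projection):
        # ~300 m apart (0.0027 deg lat), 2 h apart
        a = make_detection("a", lat=19.0, confidence=85, when="2024-03-13T04:00Z")
        b = make_detection("b", lat=19.0027, confidence=92, when="2024-03-13T06:00Z")
        assert haversine_m(a.lon, a.lat, b.lon, b.lat) < 500
        out = deduplicate([a, b])
        assert [d.id for d in out] == ["b"]

    def test_separated_pair_both_retained(self):
        # ~600 m apart, simultaneous
        a = make_detection("a", lat=19.0)
        b = make_detection("b", lat=19.0054)
        assert haversine_m(a.lon, a.lat, b.lon, b.lat) > 500
        assert len(deduplicate([a, b])) == 2

    def test_chain_keeps_endpoints(self):
        # A-B 400 m, B-C 400 m, A-C 800 m; confidences 95/90/85
        a = make_detection("a", lat=19.0, confidence=95)
        b = make_detection("b", lat=19.0036, confidence=90)
        c = make_detection("c", lat=19.0072, confidence=85)
        out = deduplicate([a, b, c])
        assert sorted(d.id for d in out) == ["a", "c"]

    def test_idempotent(self):
        dets = random_detections(200, seed=5)
        once = deduplicate(dets)
        assert [d.id for d in deduplicate(once)] == [d.id for d in once]

    def test_agrees_with_brute_force_oracle(self):
        dets = random_detections(300, seed=11)
        fast = {d.id for d in deduplicate(dets)}
        slow = {d.id for d in brute_force_dedup(dets)}
        assert fast == slow

    def test_survivor_confidence_dominates_suppressed(self):
        dets = random_detections(250, seed=3)
        out = deduplicate(dets)
        kept = {d.id for d in out}
        dropped = [d for d in dets if d.id not in kept]
        for d in dropped:
            cover = [
                s
                for s in out
                if haversine_m(s.lon, s.lat, d.lon, d.lat) <= 500
                and abs((s.acq_time - d.acq_time).total_seconds()) <= 24 * 3600
            ]
            assert cover and max(s.confidence for s in cover) >= d.confidence

    def test_commutes_with_confidence_filter(self):
        dets = random_detections(250, seed=9)
        a = filter_confidence(deduplicate(filter_confidence(dets, 80)), 80)
        b = deduplicate(filter_confidence(dets, 80))
        assert [d.id for d in a] == [d.id for d in b]

    def test_negative_arguments_rejected(self):
        with pytest.raises(ArgumentError):
            deduplicate([], radius_m=-1)
        with pytest.raises(ArgumentError):
            deduplicate([], window_h=-1)


class TestClipToRegion:
    def make_mask(self):
        return RegionMask(
            [
                ({"province": "01", "district": "0101", "subdistrict": "010101"},
                 box(98.0, 18.0, 99.0, 19.0)),
                ({"province": "02", "district": "0201", "subdistrict": "020101"},
                 box(99.0, 18.0, 100.0, 19.0)),
            ]
        )

    def test_point_inside_gets_codes(self):
        mask = self.make_mask()
        d = make_detection("a", lat=18.5, lon=98.5)
        (out,) = clip_to_region([d], mask)
        assert (out.province, out.district, out.subdistrict) == ("01", "0101", "010101")

    def test_point_outside_is_dropped(self):
        mask = self.make_mask()
        assert clip_to_region([make_detection("a", lat=10.0, lon=90.0)], mask) == []

    def test_shared_boundary_goes_to_smallest_code(self):
        mask = self.make_mask()
        d = make_detection("a", lat=18.5, lon=99.0)  # on the shared edge
        (out,) = clip_to_region([d], mask)
        assert out.province == "01"

    def test_invalid_polygon_rejected_on_construction(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(GeometryError):
            RegionMask(
                [({"province": "01", "district": "0101", "subdistrict": "010101"}, bowtie)]
            )
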