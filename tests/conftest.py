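"""Shared fixtures: a compact synthetic fire season reused across tests."""

from __future__ import annotations

import pandas as pd
import pytest

from firepm25.detections import FireDetection, Sensor
from firepm25.landcover import FuelParameterTable
from firepm25.pipeline import RunConfig, compute_products
from firepm25.proj import AlbersEqualArea
from firepm25.simulate import Scenario, gen_admin, gen_detections, gen_landcover


def make_detection(
    det_id="d0",
    lat=19.0,
    lon=99.0,
    when="2024-03-13T06:35:00Z",
    sensor=Sensor.MODIS,
    confidence=92.0,
    frp=25.4,
):
    return FireDetection(
        id=det_id,
        lat=lat,
        lon=lon,
        acq_time=pd.Timestamp(when),
        sensor=sensor,
        confidence=confidence,
        frp=frp,
    )


@pytest.fixture(scope="session")
def projection():
    return AlbersEqualArea()


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced but structurally complete season (sub-degree domain)."""
    return Scenario(seed=7, bbox=(98.6, 18.5, 99.4, 19.1), base_rate=1.5)


@pytest.fixture(scope="session")
def fuel_table():
    return FuelParameterTable.default()


@pytest.fixture(scope="session")
def small_world(small_scenario, fuel_table):
    """(scenario, landcover grid, admin mask, detections, truth ledgers)."""
    grid = gen_landcover(small_scenario)
    mask = gen_admin(small_scenario)
    dets, fires, obs = gen_detections(small_scenario, grid, fuel_table)
    return small_scenario, grid, mask, dets, fires, obs


@pytest.fixture(scope="session")
def small_run(small_world, fuel_table):
    """A full pipeline result over the compact season."""
    from firepm25.detections import clip_to_region, deduplicate, filter_confidence

    scn, grid, mask, dets, fires, obs = small_world
    cfg = RunConfig()
    clean = clip_to_region(
        deduplicate(filter_confidence(dets, cfg.min_conf)), mask
    )
    result = compute_products(clean, mask, grid, fuel_table, cfg)
    return scn, cfg, mask, result
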