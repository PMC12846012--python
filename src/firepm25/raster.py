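"""Minimal GeoTIFF reading/writing for north-up EPSG:4326 rasters.

Rasters in this package (land-cover grids, daily emission maps) are plain
single-band, north-up grids in geographic coordinates, written as GeoTIFFs
with the standard ModelPixelScale / ModelTiepoint / GeoKeyDirectory tags so
that GIS software georeferences them correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GTModelType=geographic, GTRasterType=PixelIsArea, GeographicType=EPSG:4326
_GEO_KEYS_4326 = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass(frozen=True)
class GridGeoref:
    """North-up geographic georeference: origin is the raster's top-left
    corner; ``dx``/``dy`` are positive cell sizes in degrees."""

    west: float
    north: float
    dx: float
    dy: float
    ncols: int
    nrows: int

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.dx

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.dy

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(west, south, east, north) of one cell."""
        w = self.west + col * self.dx
        n = self.north - row * self.dy
        return (w, n - self.dy, w + self.dx, n)

    def index(self, lon, lat):
        """(row, col) of the cell containing a point; may be out of range."""
        col = np.floor((np.asarray(lon) - self.west) / self.dx).astype(int)
        row = np.floor((self.north - np.asarray(lat)) / self.dy).astype(int)
        return row, col

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.ncols) + 0.5) * self.dx

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.nrows) + 0.5) * self.dy


def write_geotiff(path, data: np.ndarray, georef: GridGeoref, nodata=None) -> None:
    """Write a single-band north-up EPSG:4326 GeoTIFF."""
    if data.shape != (georef.nrows, georef.ncols):
        raise ValueError(
            f"data shape {data.shape} does not match georef "
            f"({georef.nrows}, {georef.ncols})"
        )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (georef.dx, georef.dy, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, georef.west, georef.north, 0.0), True),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS_4326), _GEO_KEYS_4326, True),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata), True))
    tifffile.imwrite(path, data, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GridGeoref]:
    """Read a single-band north-up GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    dx, dy = float(scale[0]), float(scale[1])
    west, north = float(tie[3]), float(tie[4])
    georef = GridGeoref(west=west, north=north, dx=dx, dy=dy,
                        ncols=data.shape[1], nrows=data.shape[0])
    return data, georef
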