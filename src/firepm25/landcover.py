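"""Land-cover assignment and fuel parameters.

Fire events are intersected with a 500 m land-cover grid using the 17-class
IGBP legend (MCD12Q1 Type-1 scheme) to assign each event the single class
covering the largest share of its burned area.  The class keys a fuel
parameter table holding, per class, the biomass (fuel) loading B
(kg dry matter m⁻²), combustion completeness C (fraction consumed) and
PM2.5 emission factor EF (g PM2.5 per kg dry matter burned) — the B, C and
EF terms of the emission equation E = A·B·C·EF.

The shipped default table carries FINN-style magnitudes by class and is
configuration, not a calibrated result: operational deployments replace it
with locally calibrated values loaded through :func:`load_parameters`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import transform

from .burnarea import FireEvent
from .errors import ArgumentError, GeometryError, ValidationError
from .proj import AlbersEqualArea
from .raster import GridGeoref, read_geotiff, write_geotiff

#: IGBP Type-1 class codes and names.
IGBP_NAMES = {
    1: "evergreen needleleaf forest",
    2: "evergreen broadleaf forest",
    3: "deciduous needleleaf forest",
    4: "deciduous broadleaf forest",
    5: "mixed forest",
    6: "closed shrubland",
    7: "open shrubland",
    8: "woody savanna",
    9: "savanna",
    10: "grassland",
    11: "permanent wetland",
    12: "cropland",
    13: "urban and built-up",
    14: "cropland/natural vegetation mosaic",
    15: "snow and ice",
    16: "barren",
    17: "water",
}

#: Default grouping for land-use summaries.  Savannas are grouped with
#: forest (dry dipterocarp woodland burns like open forest in this region);
#: the grouping is configuration and can be overridden.
DEFAULT_GROUPS = {
    "forest": {1, 2, 3, 4, 5, 8, 9},
    "agriculture": {12, 14},
}

NODATA = 255

# Default per-class fuel parameters: (B kg/m2, C fraction, EF g/kg, burnable).
# FINN-style magnitudes: dense tropical forest carries tens of kg/m2 of fuel
# but burns incompletely; grass and crop residues are light fuels that burn
# nearly completely with lower PM2.5 emission factors.
_DEFAULT_ROWS = [
    (1, 12.0, 0.45, 15.3, True),
    (2, 28.0, 0.50, 9.1, True),
    (3, 12.0, 0.45, 15.3, True),
    (4, 13.5, 0.45, 9.1, True),
    (5, 13.0, 0.45, 12.2, True),
    (6, 5.0, 0.55, 9.3, True),
    (7, 2.0, 0.55, 9.3, True),
    (8, 4.0, 0.60, 9.3, True),
    (9, 0.9, 0.85, 8.5, True),
    (10, 0.5, 0.90, 7.2, True),
    (11, 0.8, 0.40, 9.4, True),
    (12, 0.5, 0.90, 8.3, True),
    (13, np.nan, np.nan, np.nan, False),
    (14, 0.7, 0.80, 8.3, True),
    (15, np.nan, np.nan, np.nan, False),
    (16, np.nan, np.nan, np.nan, False),
    (17, np.nan, np.nan, np.nan, False),
]


class FuelParameterTable:
    """Validated per-class fuel parameters (B, C, EF, burnable flag)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"B_kg_m2", "C_frac", "EF_g_kg", "burnable"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"fuel table missing columns {sorted(missing)}")
        frame = frame.copy()
        frame.index = frame.index.astype(int)
        for cls in IGBP_NAMES:
            if cls not in frame.index:
                raise ValidationError(f"fuel table missing land-cover class {cls}")
        for cls, row in frame.iterrows():
            if cls not in IGBP_NAMES:
                raise ValidationError(f"unknown land-cover class {cls}")
            if bool(row["burnable"]):
                if not row["B_kg_m2"] > 0:
                    raise ValidationError(f"class {cls}: B must be > 0")
                if not 0 < row["C_frac"] <= 1:
                    raise ValidationError(f"class {cls}: C must be in (0, 1]")
                if not row["EF_g_kg"] > 0:
                    raise ValidationError(f"class {cls}: EF must be > 0")
        self.frame = frame

    @classmethod
    def default(cls) -> "FuelParameterTable":
        frame = pd.DataFrame(
            _DEFAULT_ROWS, columns=["class", "B_kg_m2", "C_frac", "EF_g_kg", "burnable"]
        ).set_index("class")
        return cls(frame)

    def is_burnable(self, lc_class: int) -> bool:
        return bool(self.frame.loc[int(lc_class), "burnable"])

    def params(self, lc_class: int) -> tuple[float, float, float]:
        """(B, C, EF) for a burnable class; zeros for non-burnable."""
        row = self.frame.loc[int(lc_class)]
        if not bool(row["burnable"]):
            return (0.0, 0.0, 0.0)
        return (float(row["B_kg_m2"]), float(row["C_frac"]), float(row["EF_g_kg"]))

    def emission_product(self, lc_class: int) -> float:
        """B·C·EF, used for health-protective tie-breaking (0 if non-burnable)."""
        b, c, ef = self.params(lc_class)
        return b * c * ef

    def to_csv(self, path) -> None:
        out = self.frame.reset_index().rename(columns={"index": "class"})
        out.to_csv(path, index=False)


def load_parameters(source) -> FuelParameterTable:
    """Load and validate a fuel parameter CSV (class,B_kg_m2,C_frac,EF_g_kg,burnable)."""
    frame = pd.read_csv(source)
    if "class" not in frame.columns:
        raise ValidationError("fuel table missing column 'class'")
    return FuelParameterTable(frame.set_index("class"))


def lc_group(lc_class: int, groups: dict[str, set[int]] | None = None) -> str:
    """Land-use category of a class: 'forest', 'agriculture' or 'other'."""
    lc_class = int(lc_class)
    if lc_class not in IGBP_NAMES:
        raise ArgumentError(f"unknown land-cover class {lc_class}")
    groups = DEFAULT_GROUPS if groups is None else groups
    for name, members in groups.items():
        if lc_class in members:
            return name
    return "other"


@dataclass
class LandCoverGrid:
    """Georeferenced raster of IGBP class codes (~500 m cells, EPSG:4326)."""

    data: np.ndarray  # uint8, row 0 = north
    georef: GridGeoref
    nodata: int = NODATA

    @classmethod
    def from_geotiff(cls, path) -> "LandCoverGrid":
        data, georef = read_geotiff(path)
        return cls(data=np.asarray(data), georef=georef)

    def to_geotiff(self, path) -> None:
        write_geotiff(path, self.data.astype(np.uint8), self.georef, nodata=self.nodata)

    def class_at(self, lon: float, lat: float) -> int | None:
        row, col = self.georef.index(lon, lat)
        if 0 <= row < self.georef.nrows and 0 <= col < self.georef.ncols:
            v = int(self.data[row, col])
            return None if v == self.nodata else v
        return None

    def class_fractions(self) -> dict[int, float]:
        """Realized areal fraction per class (no-data excluded)."""
        vals, counts = np.unique(self.data[self.data != self.nodata], return_counts=True)
        total = counts.sum()
        return {int(v): c / total for v, c in zip(vals, counts)}


def assign_class(
    event: FireEvent,
    grid: LandCoverGrid,
    table: FuelParameterTable | None = None,
    projection: AlbersEqualArea | None = None,
) -> int:
    """Majority-area land-cover class of an event polygon.

    Intersection areas are measured in the equal-area projected frame.
    Ties are broken in favour of the class with the larger B·C·EF product
    (the health-protective choice); no-data cells are excluded.  An event
    lying entirely over no-data raises :class:`GeometryError`.
    """
    if event.geometry_lonlat is None:
        raise GeometryError(f"event {event.event_id} lacks geographic geometry")
    table = table or FuelParameterTable.default()
    proj = projection or AlbersEqualArea()
    g = grid.georef
    minx, miny, maxx, maxy = event.geometry_lonlat.bounds
    row0, col0 = g.index(minx, maxy)
    row1, col1 = g.index(maxx, miny)
    row0, row1 = max(0, int(row0)), min(g.nrows - 1, int(row1))
    col0, col1 = max(0, int(col0)), min(g.ncols - 1, int(col1))

    def fwd(x, y):
        return proj.forward(np.asarray(x), np.asarray(y))

    areas: dict[int, float] = {}
    for r in range(row0, row1 + 1):
        for c in range(col0, col1 + 1):
            v = int(grid.data[r, c])
            if v == grid.nodata:
                continue
            w, s, e, n = g.cell_bounds(r, c)
            inter = event.geometry_lonlat.intersection(box(w, s, e, n))
            if inter.is_empty:
                continue
            areas[v] = areas.get(v, 0.0) + transform(fwd, inter).area
    if not areas:
        raise GeometryError(
            f"event {event.event_id} lies entirely over no-data land cover"
        )
    # areas equal to the maximum within floating-point tolerance are ties
    amax = max(areas.values())
    tied = [k for k, v in areas.items() if v >= amax * (1.0 - 1e-9)]
    return max(tied, key=lambda k: (table.emission_product(k), -k))
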