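"""Published 2024 fire-season reference figures for Upper Northern Thailand.

The operational system's published January–April 2024 provincial summary
(total, forest and agricultural land areas and biomass-burning PM2.5
emissions for the eight Upper North provinces) and the published regional
emission–concentration regression are shipped here as inputs.  They let
the package reproduce the season's summary arithmetic — emission
densities, land-use intensities, provincial shares, monthly means and the
Emission Control Threshold — without access to the underlying satellite
and monitoring-station archives.
"""

from __future__ import annotations

import pandas as pd

from .analytics import EmissionUnit, RegressionResult

#: Province rows: (name, total km², total tons, forest km², forest tons,
#: agricultural km², agricultural tons) for January–April 2024.
_PROVINCES = [
    ("Chiang Mai",   22135, 70179, 15037, 62421, 5475, 6631),
    ("Chiang Rai",   11503, 21008,  4441, 17072, 5905, 3320),
    ("Lampang",      12488, 34297,  8721, 31775, 2844, 2223),
    ("Lamphun",       4478,  8236,  2600,  7545, 2844,  525),
    ("Mae Hong Son", 12765, 69141, 10655, 62469, 1821, 5956),
    ("Nan",          12130, 36773,  7359, 30544, 4395, 5366),
    ("Phayao",        6189, 17644,  3221, 15870, 2485, 1527),
    ("Phrae",         6783, 14273,  4793, 12566, 1905, 1433),
]

#: Months spanned by the published season window (January–April).
SEASON_MONTHS = 4


def provincial_summary_2024() -> pd.DataFrame:
    """Published provincial areas and PM2.5 emissions, Jan–Apr 2024."""
    return pd.DataFrame(
        _PROVINCES,
        columns=[
            "province",
            "total_area_km2",
            "total_tons",
            "forest_area_km2",
            "forest_tons",
            "agri_area_km2",
            "agri_tons",
        ],
    ).set_index("province")


#: Published regional regression of daily mean PM2.5 (µg m⁻³) on the daily
#: biomass-burning emission rate, 2024 season (X in kg/day: the printed
#: slope magnitude is only consistent with the printed threshold under the
#: kilogram reading, so the unit is recorded explicitly).
REFERENCE_ALPHA = 40.41
REFERENCE_BETA_PER_KG = 0.00000631343
REFERENCE_R = 0.67
REFERENCE_R2 = 0.448
REFERENCE_P = 6.483e-17

#: Operational PM2.5 decision benchmark (µg m⁻³), consistent with regional
#: warning levels; stricter than it sounds because the no-burning baseline
#: alpha already sits above the national 24 h standard of 37.5 µg m⁻³.
DEFAULT_Y_TARGET = 50.0


def reference_regression(n: int = 121) -> RegressionResult:
    """The published 2024-season emission–concentration regression."""
    return RegressionResult(
        alpha=REFERENCE_ALPHA,
        beta=REFERENCE_BETA_PER_KG,
        r=REFERENCE_R,
        r2=REFERENCE_R2,
        p=REFERENCE_P,
        n=n,
        x_unit=EmissionUnit.KG_PER_DAY,
    )
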