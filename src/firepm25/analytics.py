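"""Validation statistics and decision support.

Links daily biomass-burning emissions to surface PM2.5: Pearson
correlation against fire radiative power, ordinary-least-squares regression
of regional-mean PM2.5 concentration on the daily emission rate
(Y = α + βX), and inversion of that regression at a target concentration
to obtain the Emission Control Threshold X* — the maximum daily emission
load compatible with keeping PM2.5 at or below the target.  The threshold
then drives exceedance classification and burn-permit screening.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .aggregate import DailySeries
from .errors import ArgumentError
from .landcover import FuelParameterTable
from .emission import compute_emission


class EmissionUnit(str, enum.Enum):
    """Unit of the regression predictor X (daily emission rate)."""

    KG_PER_DAY = "kg/day"
    TONS_PER_DAY = "tons/day"


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear fit Y[µg m⁻³] = alpha + beta · X[x_unit]."""

    alpha: float
    beta: float
    r: float
    r2: float
    p: float
    n: int
    x_unit: EmissionUnit
    alpha_ci: tuple[float, float] | None = None
    beta_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class Threshold:
    """Emission Control Threshold: maximum permissible daily emission."""

    y_target: float  # µg/m³
    x_star: float  # tons/day, floored to integer tons
    provenance: RegressionResult


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length series (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ArgumentError("series must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ArgumentError("zero variance in input series")
    return float(np.corrcoef(x, y)[0, 1])


def fit_ols(
    emissions, pm25, x_unit: EmissionUnit = EmissionUnit.TONS_PER_DAY
) -> RegressionResult:
    """OLS of daily PM2.5 concentration on the daily emission rate.

    ``pm25`` is the regional mean over retained stations.  Returns the
    intercept α (baseline concentration with no burning), slope β, Pearson
    r, R², the two-sided t-test p-value for β, and 95% confidence
    intervals for both coefficients.
    """
    x = np.asarray(emissions, dtype=float)
    y = np.asarray(pm25, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ArgumentError("need paired daily series of length >= 3")
    if np.ptp(x) == 0:
        raise ArgumentError("emission series is constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else 0.0
    return RegressionResult(
        alpha=float(model.params[0]),
        beta=float(model.params[1]),
        r=r,
        r2=float(r * r),
        p=float(model.pvalues[1]),
        n=int(x.size),
        x_unit=EmissionUnit(x_unit),
        alpha_ci=(float(ci[0][0]), float(ci[0][1])),
        beta_ci=(float(ci[1][0]), float(ci[1][1])),
    )


def invert_threshold(res: RegressionResult, y_target: float = 50.0) -> Threshold:
    """Invert Y = α + βX at a target concentration (default 50 µg m⁻³).

    X* = floor of (y_target − α)/β expressed in tons/day (flooring is the
    health-protective rounding: operating at X* keeps the predicted
    concentration at or below the target).  Raises if the no-burning
    baseline α already exceeds the target — then no emission is
    permissible.
    """
    if res.beta <= 0:
        raise ArgumentError("regression slope must be positive to invert")
    if res.alpha >= y_target:
        raise ArgumentError(
            f"baseline exceeds target: alpha={res.alpha} >= y_target={y_target}; "
            "no permissible emission"
        )
    x_native = (y_target - res.alpha) / res.beta
    tons = x_native / 1000.0 if res.x_unit is EmissionUnit.KG_PER_DAY else x_native
    # snap values within float rounding of an integer before flooring, so an
    # exactly-invertible target is not pushed down a whole ton
    nearest = round(tons)
    if abs(tons - nearest) <= 1e-9 * max(1.0, abs(tons)):
        tons = nearest
    return Threshold(y_target=y_target, x_star=float(math.floor(tons)), provenance=res)


def classify_days(series: DailySeries, th: Threshold) -> dict:
    """Flag each day as within/exceed relative to the threshold.

    A day exceeds when its emission total is strictly greater than X*
    (operating exactly at the threshold is compliant).  Reports the flags,
    the exceedance count, and the lengths of consecutive exceedance runs.
    """
    daily = series.daily
    exceed = daily > th.x_star
    runs: list[int] = []
    current = 0
    for flag in exceed.to_numpy():
        if flag:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return {
        "flags": exceed.map({True: "exceed", False: "within"}),
        "n_exceed": int(exceed.sum()),
        "n_days": int(len(daily)),
        "runs": runs,
    }


def screen_request(
    request: dict, context: dict, table: FuelParameterTable | None = None
) -> dict:
    """Screen a burn-permit request against the Emission Control Threshold.

    ``request``: area_km2, lc_class (and date, informational).
    ``context``: committed_tons_today, threshold (:class:`Threshold`),
    forecast_flag ('favorable' | 'adverse').

    Restrict when committed + projected emissions would exceed X* or when
    the dispersion forecast is adverse; otherwise authorize as managed
    biomass burning.  Non-burnable land cover authorizes with zero
    projected emissions and an advisory note.
    """
    table = table or FuelParameterTable.default()
    lc_class = int(request["lc_class"])
    th: Threshold = context["threshold"]
    committed = float(context.get("committed_tons_today", 0.0))
    adverse = context.get("forecast_flag", "favorable") == "adverse"
    if not table.is_burnable(lc_class):
        return {
            "decision": "authorize",
            "projected_tons": 0.0,
            "note": "non-burnable land cover; no biomass-burning emission expected",
        }
    projected = compute_emission(float(request["area_km2"]), table.params(lc_class))
    over = committed + projected > th.x_star
    decision = "restrict" if (over or adverse) else "authorize"
    note = (
        "projected load exceeds the Emission Control Threshold"
        if over
        else ("adverse dispersion forecast" if adverse else "managed biomass burning")
    )
    return {"decision": decision, "projected_tons": projected, "note": note}


def spatial_corr(
    frp_stack: np.ndarray, emis_stack: np.ndarray, min_days: int = 3
) -> np.ndarray:
    """Per-cell Pearson r between daily FRP and emission stacks.

    Both stacks are (time, rows, cols) and must be aligned.  Cells with
    fewer than ``min_days`` fire-active days or zero variance in either
    field are masked (NaN).
    """
    frp = np.asarray(frp_stack, dtype=float)
    emis = np.asarray(emis_stack, dtype=float)
    if frp.shape != emis_stack.shape:
        raise ArgumentError("FRP and emission stacks are misaligned")
    t = frp.shape[0]
    active = ((frp > 0) | (emis > 0)).sum(axis=0)
    fm = frp.mean(axis=0)
    em = emis.mean(axis=0)
    fa = frp - fm
    ea = emis - em
    cov = (fa * ea).sum(axis=0) / t
    sf = np.sqrt((fa ** 2).sum(axis=0) / t)
    se = np.sqrt((ea ** 2).sum(axis=0) / t)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sf * se)
    r[(active < min_days) | (sf == 0) | (se == 0)] = np.nan
    return r
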