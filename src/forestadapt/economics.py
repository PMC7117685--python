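"""Timber and carbon economics.

Stand volume and stand carbon follow saturating Chapman–Richards curves of
stand age.  Timber profitability is annualized with the Faustmann land
expectation value: the optimal rotation T* maximizes

    LEV(T) = (p · V(T) − c) · e^(−rT) / (1 − e^(−rT)),

the present value of an infinite sequence of identical rotations, and the
annual timber rent is r · LEV(T*).  A carbon-pricing policy pays a standing
rent proportional to the stand's mean annual carbon increment over the
rotation, and charges a tax proportional to the carbon released when a stand
is cut.  The effective rent entering replant decisions is the sum of timber
and carbon rents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

from .core import FOREST_TYPES

__all__ = [
    "YieldCurve",
    "CarbonYieldCurve",
    "YieldCurveFit",
    "CarbonPriceSchedule",
    "RentTable",
    "fit_yield_curve",
    "annual_timber_rent",
    "carbon_price_at",
    "carbon_rent",
    "harvest_carbon_tax",
    "effective_rent",
    "MAIN_SCHEDULE",
    "LOW_SCHEDULE",
    "HIGH_SCHEDULE",
    "default_yield_curves",
    "default_carbon_curves",
]


def _chapman_richards(age, v_max, k, theta):
    age = np.asarray(age, float)
    return v_max * np.power(-np.expm1(-k * age), theta)


@dataclass(frozen=True)
class YieldCurve:
    """Merchantable volume (m³/ha) as a function of stand age (yr)."""

    forest_type: str
    v_max: float  # m³/ha asymptote
    k: float      # 1/yr approach rate
    theta: float  # shape exponent

    def __post_init__(self):
        if self.v_max < 0 or self.k <= 0 or self.theta <= 0:
            raise ValueError("yield curve requires v_max >= 0, k > 0, theta > 0")

    def __call__(self, age):
        return _chapman_richards(age, self.v_max, self.k, self.theta)

    def scaled(self, multiplier: float) -> "YieldCurve":
        """Curve with the asymptote scaled (e.g. by an NPP multiplier)."""
        return YieldCurve(self.forest_type, self.v_max * multiplier, self.k, self.theta)


@dataclass(frozen=True)
class CarbonYieldCurve:
    """Stand carbon (tC/ha) as a function of stand age (yr)."""

    forest_type: str
    c_max: float
    k_c: float
    theta_c: float

    def __post_init__(self):
        if self.c_max < 0 or self.k_c <= 0 or self.theta_c <= 0:
            raise ValueError("carbon curve requires c_max >= 0, k_c > 0, theta_c > 0")

    def __call__(self, age):
        return _chapman_richards(age, self.c_max, self.k_c, self.theta_c)

    def scaled(self, multiplier: float) -> "CarbonYieldCurve":
        return CarbonYieldCurve(
            self.forest_type, self.c_max * multiplier, self.k_c, self.theta_c
        )


@dataclass(frozen=True)
class YieldCurveFit:
    """A fitted yield curve with goodness-of-fit diagnostics."""

    curve: YieldCurve
    residual_norm: float
    converged: bool
    message: str = ""

    @property
    def degenerate(self) -> bool:
        """True when the fitted asymptote is effectively zero."""
        return self.curve.v_max < 1e-6


def fit_yield_curve(
    observations: Sequence[tuple[float, float]], forest_type: str
) -> YieldCurveFit:
    """Least-squares fit of a Chapman–Richards volume curve to (age, volume) data.

    Raises ValueError for fewer than 4 observations or all-identical ages;
    non-convergence is reported on the returned object, never silently.
    """
    obs = np.asarray(observations, float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 4:
        raise ValueError("need at least 4 (age, volume) observations")
    ages, vols = obs[:, 0], obs[:, 1]
    if np.ptp(ages) == 0:
        raise ValueError("degenerate input: all observations share one age")
    if np.all(vols <= 0):
        return YieldCurveFit(
            YieldCurve(forest_type, 0.0, 0.05, 1.0),
            residual_norm=float(np.linalg.norm(vols)),
            converged=True,
            message="all volumes <= 0; flat zero curve",
        )
    v0 = max(vols.max() * 1.1, 1.0)
    try:
        popt, _ = curve_fit(
            _chapman_richards,
            ages,
            vols,
            p0=(v0, 0.05, 1.5),
            bounds=([0.0, 1e-4, 1e-2], [np.inf, 2.0, 20.0]),
            maxfev=20000,
        )
        curve = YieldCurve(forest_type, *popt)
        resid = float(np.linalg.norm(vols - curve(ages)))
        return YieldCurveFit(curve, resid, True)
    except RuntimeError as exc:  # no convergence
        return YieldCurveFit(
            YieldCurve(forest_type, v0, 0.05, 1.5),
            residual_norm=float("nan"),
            converged=False,
            message=f"curve_fit did not converge: {exc}",
        )


def _lev(T, curve: YieldCurve, price: float, rate: float, cost: float):
    T = np.asarray(T, float)
    disc = np.exp(-rate * T)
    return (price * curve(T) - cost) * disc / (1.0 - disc)


def annual_timber_rent(
    curve: YieldCurve,
    price: float,
    discount_rate: float = 0.05,
    cost: float = 0.0,
    max_rotation: float = 300.0,
) -> tuple[float, float | None]:
    """Faustmann-annualized timber rent ($/ha/yr) and optimal rotation (yr).

    Returns (0.0, None) when no rotation yields a positive land expectation
    value (e.g. zero price).
    """
    if price < 0:
        raise ValueError("price must be nonnegative")
    if not 0.0 < discount_rate < 1.0:
        raise ValueError("discount_rate must be in (0, 1)")
    if price == 0.0 or curve.v_max <= 0.0:
        return 0.0, None
    # Coarse bracket, then continuous refinement inside the winning bracket.
    grid = np.linspace(0.5, max_rotation, 600)
    vals = _lev(grid, curve, price, discount_rate, cost)
    i = int(np.argmax(vals))
    if vals[i] <= 0.0:
        return 0.0, None
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda T: -_lev(T, curve, price, discount_rate, cost),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    T_star = float(res.x)
    lev = float(_lev(T_star, curve, price, discount_rate, cost))
    return discount_rate * lev, T_star


@dataclass(frozen=True)
class CarbonPriceSchedule:
    """Right-continuous step function of carbon price ($/tC) over calendar years."""

    steps: tuple[tuple[int, float], ...]

    def __post_init__(self):
        years = [y for y, _ in self.steps]
        if not years:
            raise ValueError("schedule needs at least one step")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("step years must be strictly increasing")
        if any(p < 0 for _, p in self.steps):
            raise ValueError("prices must be nonnegative")

    def price_at(self, year: float) -> float:
        if year < self.steps[0][0]:
            raise ValueError(f"year {year} precedes schedule start {self.steps[0][0]}")
        price = self.steps[0][1]
        for start, p in self.steps:
            if year >= start:
                price = p
        return price


#: The three carbon-price schedules considered in the scenario analysis.
MAIN_SCHEDULE = CarbonPriceSchedule(((2020, 15.0), (2050, 50.0), (2080, 80.0)))
LOW_SCHEDULE = CarbonPriceSchedule(((2020, 15.0), (2050, 30.0), (2080, 50.0)))
HIGH_SCHEDULE = CarbonPriceSchedule(((2020, 30.0), (2050, 60.0), (2080, 100.0)))


def carbon_price_at(year: float, schedule: CarbonPriceSchedule) -> float:
    """Carbon price ($/tC) in force at ``year`` under a step schedule."""
    return schedule.price_at(year)


def carbon_rent(curve: CarbonYieldCurve, price_c: float, rotation: float) -> float:
    """Annual carbon rent: price times mean annual carbon increment over the rotation."""
    if rotation <= 0:
        raise ValueError("rotation must be positive")
    return price_c * float(curve(rotation)) / rotation


def harvest_carbon_tax(
    curve: CarbonYieldCurve,
    stand_age: float,
    price_c: float,
    release_fraction: float = 0.5,
) -> float:
    """One-off tax ($/ha) on carbon released by cutting a stand of the given age."""
    if stand_age < 0:
        raise ValueError("stand_age must be nonnegative")
    if not 0.0 <= release_fraction <= 1.0:
        raise ValueError("release_fraction must be in [0, 1]")
    return price_c * release_fraction * float(curve(stand_age))


def effective_rent(timber_rent: float, carbon_rent_: float) -> float:
    """Carbon-augmented rent entering replant utilities: simple sum."""
    return timber_rent + carbon_rent_


# ---------------------------------------------------------------------------
# Default curves and regional rent tables


def default_yield_curves() -> dict[str, YieldCurve]:
    """Stylized volume curves per forest type (m³/ha over age in years).

    Levels and shapes are chosen to mimic Pacific-coast silvics: Douglas-fir
    and hemlock/sitka-spruce highly productive, ponderosa pine and hardwoods
    slower/lower, hardwoods reaching merchantable volume earliest.
    """
    spec = {
        "DF": (650.0, 0.035, 2.2),
        "FSM": (480.0, 0.028, 2.0),
        "HSS": (700.0, 0.038, 2.2),
        "PP": (320.0, 0.030, 1.8),
        "OSW": (300.0, 0.032, 1.8),
        "HW": (280.0, 0.055, 1.6),
    }
    return {t: YieldCurve(t, *spec[t]) for t in FOREST_TYPES}


def default_carbon_curves() -> dict[str, CarbonYieldCurve]:
    """Stylized stand-carbon curves (tC/ha over age in years).

    Hardwoods sequester fast early (high k_c), giving them the largest mean
    annual increment over short rotations even though conifers store more
    carbon at maturity.
    """
    spec = {
        "DF": (260.0, 0.030, 2.0),
        "FSM": (210.0, 0.025, 2.0),
        "HSS": (280.0, 0.032, 2.0),
        "PP": (150.0, 0.028, 1.8),
        "OSW": (140.0, 0.030, 1.8),
        "HW": (190.0, 0.065, 1.5),
    }
    return {t: CarbonYieldCurve(t, *spec[t]) for t in FOREST_TYPES}


#: Stylized timber prices ($/m³) per forest type; conifer sawtimber commands
#: a premium over hardwood pulp in Pacific-coast markets.
DEFAULT_PRICES = {
    "DF": 55.0,
    "FSM": 40.0,
    "HSS": 50.0,
    "PP": 35.0,
    "OSW": 30.0,
    "HW": 25.0,
}


@dataclass
class RentTable:
    """Annual timber rents by (ecoregion, forest type) plus the price vector used.

    ``table`` columns: ecoregion_id, forest_type, rent ($/ha/yr),
    optimal_rotation (yr or NaN when unprofitable).
    """

    table: pd.DataFrame
    prices: dict[str, float]

    def rent(self, ecoregion_id: int, forest_type: str) -> float:
        sel = self.table[
            (self.table.ecoregion_id == ecoregion_id)
            & (self.table.forest_type == forest_type)
        ]
        if sel.empty:
            raise KeyError((ecoregion_id, forest_type))
        return float(sel.rent.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, prices: dict[str, float]) -> "RentTable":
        return cls(pd.read_csv(path), dict(prices))


def build_rent_table(
    ecoregion_ids: Sequence[int],
    yield_curves: dict[str, YieldCurve],
    prices: dict[str, float],
    discount_rate: float = 0.05,
    cost: float = 0.0,
    npp_multipliers: dict[tuple[str, int], float] | None = None,
) -> RentTable:
    """Regional annual timber rents from Faustmann annualization.

    ``npp_multipliers`` optionally scales each (forest_type, ecoregion)
    curve's asymptote before annualization (productivity adjustment).
    """
    rows = []
    for eco in ecoregion_ids:
        for t in FOREST_TYPES:
            curve = yield_curves[t]
            if npp_multipliers is not None:
                curve = curve.scaled(npp_multipliers.get((t, eco), 1.0))
            rent, rot = annual_timber_rent(curve, prices[t], discount_rate, cost)
            rows.append(
                {
                    "ecoregion_id": eco,
                    "forest_type": t,
                    "rent": rent,
                    "optimal_rotation": np.nan if rot is None else rot,
                }
            )
    return RentTable(pd.DataFrame(rows), dict(prices))
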