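"""Decadal stochastic landscape simulation.

Starting from the current landscape state, landowner decisions are simulated
at 2020, 2030, …, 2090 (states reported through 2100): each plot-decade a
management outcome (k, j) is drawn from the nested-logit probabilities under
the scenario's climate, prices, productivity multipliers, and carbon-price
schedule, and the stand state is advanced accordingly.  Replicates use
independent substreams of a master seed, consumed in an identical order
across scenarios (common random numbers), so scenario effects can be
isolated by differencing ensembles run with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .choice import build_utilities, joint_matrix, nested_forward
from .core import (
    CLIMATE_VARS,
    DISTURBANCE_OUTCOMES,
    FOREST_TYPES,
    ChoiceConfig,
    ChoiceParameters,
    viable_types_from_str,
)
from .economics import (
    DEFAULT_PRICES,
    CarbonPriceSchedule,
    HIGH_SCHEDULE,
    LOW_SCHEDULE,
    MAIN_SCHEDULE,
    annual_timber_rent,
    carbon_price_at,
    carbon_rent,
    default_carbon_curves,
    default_yield_curves,
    effective_rent,
)
from .synthetic import ClimateTrajectory, generate_climate_trajectory

__all__ = [
    "Scenario",
    "LandscapeState",
    "SimulationEnsemble",
    "LandscapeSimulator",
    "make_scenario",
    "initial_state",
    "step_decade",
    "run_simulation",
    "composition_series",
    "composition_difference",
]

SCENARIO_NAMES = (
    "baseline",
    "climate_only",
    "climate_carbon_main",
    "climate_carbon_low",
    "climate_carbon_high",
)
_SCHEDULES = {
    "climate_carbon_main": MAIN_SCHEDULE,
    "climate_carbon_low": LOW_SCHEDULE,
    "climate_carbon_high": HIGH_SCHEDULE,
}
DECISION_YEARS = tuple(range(2020, 2091, 10))
REPORT_DECADES = tuple(range(2020, 2101, 10))


def default_npp_multipliers(
    plots: pd.DataFrame, decline_df: float = 0.15, decline_conifer: float = 0.07
) -> dict[tuple[str, int], np.ndarray]:
    """Per-decade productivity multipliers by (forest type, ecoregion).

    Douglas-fir productivity declines linearly through 2100 in proportion to
    how warm the ecoregion already is (other non-pine conifers decline at
    half that rate); hardwood productivity stays at 1.0.
    """
    warmth = plots.groupby("ecoregion_id")["gs_tmean"].mean()
    w = (warmth - warmth.min()) / max(warmth.max() - warmth.min(), 1e-9)
    progress = (np.array(REPORT_DECADES) - 2020) / 80.0
    out: dict[tuple[str, int], np.ndarray] = {}
    for eco, wv in w.items():
        for t in FOREST_TYPES:
            if t == "DF":
                d = decline_df * wv
            elif t in ("FSM", "HSS"):
                d = decline_conifer * wv
            else:
                d = 0.0
            out[(t, int(eco))] = 1.0 - d * progress
    return out


@dataclass
class Scenario:
    """A named bundle of exogenous trajectories driving one simulation run."""

    name: str
    climate: ClimateTrajectory
    price_multiplier: dict[int, float]
    npp: dict[tuple[str, int], np.ndarray] | None = None
    carbon: CarbonPriceSchedule | None = None
    release_fraction: float = 0.5
    discount_rate: float = 0.05

    def __post_init__(self):
        if self.name == "baseline":
            if not self.climate.is_zero:
                raise ValueError("baseline scenario must have zero climate deltas")
            if self.carbon is not None:
                raise ValueError("baseline scenario has no carbon schedule")
        if self.name == "climate_only" and self.carbon is not None:
            raise ValueError("climate_only scenario has no carbon schedule")

    def prices_at(self, decade: int) -> dict[str, float]:
        mult = self.price_multiplier.get(decade, 1.0)
        return {t: DEFAULT_PRICES[t] * mult for t in FOREST_TYPES}

    def npp_at(self, forest_type: str, ecoregion: int, decade: int) -> float:
        if self.npp is None:
            return 1.0
        arr = self.npp.get((forest_type, ecoregion))
        if arr is None:
            return 1.0
        return float(arr[REPORT_DECADES.index(decade)])


def make_scenario(
    name: str,
    plots: pd.DataFrame,
    warming_total: float = 4.0,
    drying_total: float = 80.0,
    price_trend: float = 0.0,
) -> Scenario:
    """Build one of the five named scenarios with default trajectories.

    ``price_trend`` is a per-decade relative drift of all timber prices
    (default flat; global price forecasts are exogenous inputs).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    kind = "baseline" if name == "baseline" else "warming"
    climate = generate_climate_trajectory(kind, 8, warming_total, drying_total)
    mult = {
        d: (1.0 + price_trend) ** ((d - 2020) // 10) for d in REPORT_DECADES
    }
    npp = None if name == "baseline" else default_npp_multipliers(plots)
    return Scenario(
        name=name,
        climate=climate,
        price_multiplier=mult,
        npp=npp,
        carbon=_SCHEDULES.get(name),
    )


@dataclass
class LandscapeState:
    """Per-plot stand state at one decade."""

    decade: int
    table: pd.DataFrame  # plot_id, forest_type, stand_age, volume

    def __post_init__(self):
        if (self.table.stand_age < 0).any() or (self.table.volume < 0).any():
            raise ValueError("ages and volumes must be nonnegative")


def initial_state(plots: pd.DataFrame, decade: int = 2020) -> LandscapeState:
    return LandscapeState(
        decade,
        plots[["plot_id", "forest_type", "stand_age", "volume"]].copy(),
    )


@dataclass
class SimulationEnsemble:
    """Per-replicate, per-decade landscape states stored as dense arrays."""

    scenario_name: str
    master_seed: int
    plot_ids: np.ndarray
    decades: tuple[int, ...]
    types: np.ndarray    # (n_reps, n_decades, n_plots) int8 forest-type index
    ages: np.ndarray     # float32
    volumes: np.ndarray  # float32

    @property
    def n_replicates(self) -> int:
        return self.types.shape[0]

    def state(self, replicate: int, decade: int) -> LandscapeState:
        d = self.decades.index(decade)
        return LandscapeState(
            decade,
            pd.DataFrame(
                {
                    "plot_id": self.plot_ids,
                    "forest_type": np.array(FOREST_TYPES)[self.types[replicate, d]],
                    "stand_age": self.ages[replicate, d].astype(float),
                    "volume": self.volumes[replicate, d].astype(float),
                }
            ),
        )

    def type_count(self, forest_type: str) -> np.ndarray:
        """(n_reps, n_decades) count of plots carrying ``forest_type``."""
        return (self.types == FOREST_TYPES.index(forest_type)).sum(axis=2)

    def df_change(self, forest_type: str = "DF") -> np.ndarray:
        """Per-replicate change in the type's plot count from 2020 to 2100."""
        c = self.type_count(forest_type)
        return c[:, -1] - c[:, 0]

    def to_csv(self, path) -> None:
        rows = []
        for r in range(self.n_replicates):
            for di, d in enumerate(self.decades):
                rows.append(
                    pd.DataFrame(
                        {
                            "replicate": r,
                            "decade": d,
                            "plot_id": self.plot_ids,
                            "forest_type": np.array(FOREST_TYPES)[self.types[r, di]],
                            "stand_age": self.ages[r, di],
                            "volume": self.volumes[r, di],
                        }
                    )
                )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


class LandscapeSimulator:
    """Runs decadal landscape simulations for a fixed plot table and parameters."""

    def __init__(
        self,
        plots: pd.DataFrame,
        params: ChoiceParameters,
        config: ChoiceConfig = ChoiceConfig(),
        yield_curves=None,
        carbon_curves=None,
    ):
        params.validate()
        self.plots = plots.reset_index(drop=True)
        self.params = params
        self.config = config
        self.curves = yield_curves or default_yield_curves()
        self.carbon_curves = carbon_curves or default_carbon_curves()
        n = len(plots)
        self._clim0 = self.plots[list(CLIMATE_VARS)].to_numpy(float)
        self._elev = self.plots["elevation"].to_numpy(float)
        self._eco = self.plots["ecoregion_id"].to_numpy(int)
        self._viable = np.zeros((n, len(FOREST_TYPES)), bool)
        for i, s in enumerate(self.plots["viable_types"]):
            for t in viable_types_from_str(s):
                self._viable[i, FOREST_TYPES.index(t)] = True
        self._labels = self._alt_labels()
        self._decade_cache: dict = {}

    def _alt_labels(self):
        labels = [("clearcut", j) for j in range(len(FOREST_TYPES))]
        if self.config.partial_replant:
            labels += [("partialcut", j) for j in range(len(FOREST_TYPES))]
        else:
            labels += [("partialcut", -1)]
        labels += [("nocut", d) for d in range(len(DISTURBANCE_OUTCOMES))]
        return labels

    # -- per-decade exogenous inputs ---------------------------------------

    def effective_rents(self, scenario: Scenario, year: int) -> dict[tuple[int, str], float]:
        """Carbon-augmented annual rents per (ecoregion, forest type) at ``year``.

        Timber rents are re-annualized each decade from NPP-adjusted yield
        curves; under a carbon schedule, the carbon rent uses the replanted
        type's timber-optimal rotation (or, if timber is unprofitable, the
        rotation maximizing mean annual carbon increment).
        """
        prices = scenario.prices_at(year)
        p_c = (
            carbon_price_at(year, scenario.carbon)
            if scenario.carbon is not None
            else 0.0
        )
        out = {}
        for eco in np.unique(self._eco):
            for t in FOREST_TYPES:
                m = scenario.npp_at(t, int(eco), year)
                curve = self.curves[t].scaled(m)
                t_rent, rot = annual_timber_rent(
                    curve, prices[t], scenario.discount_rate
                )
                c_rent = 0.0
                if p_c > 0.0:
                    ccurve = self.carbon_curves[t].scaled(m)
                    if rot is None:
                        grid = np.arange(5.0, 200.0)
                        rot = float(grid[np.argmax(ccurve(grid) / grid)])
                    c_rent = carbon_rent(ccurve, p_c, rot)
                out[(int(eco), t)] = effective_rent(t_rent, c_rent)
        return out

    def _decade_inputs(self, scenario: Scenario, year: int):
        """Per-plot exogenous arrays at one decision year, cached per scenario."""
        key = (id(scenario), year)
        hit = self._decade_cache.get(key)
        if hit is not None:
            return hit
        n = len(self.plots)
        ecos = np.unique(self._eco)
        eco_pos = np.searchsorted(ecos, self._eco)
        rents_map = self.effective_rents(scenario, year)
        rents_eco = np.array(
            [[rents_map[(int(e), t)] for t in FOREST_TYPES] for e in ecos]
        )
        npp_eco = np.array(
            [
                [scenario.npp_at(t, int(e), year) for t in FOREST_TYPES]
                for e in ecos
            ]
        )
        out = {
            "clim_delta": scenario.climate.cumulative(year),
            "prices": np.array(
                [scenario.prices_at(year)[t] for t in FOREST_TYPES]
            ),
            "p_c": (
                carbon_price_at(year, scenario.carbon)
                if scenario.carbon is not None
                else 0.0
            ),
            "rents": rents_eco[eco_pos],  # (n, 6)
            "npp": npp_eco[eco_pos],      # (n, 6)
        }
        self._decade_cache[key] = out
        return out

    def _covariates(self, state: LandscapeState, scenario: Scenario, year: int):
        n = len(self.plots)
        type_idx = state.table["forest_type"].map(FOREST_TYPES.index).to_numpy()
        age = state.table["stand_age"].to_numpy(float)
        vol = state.table["volume"].to_numpy(float)
        inputs = self._decade_inputs(scenario, year)
        clim = self._clim0 + inputs["clim_delta"][None, :]
        p_c = inputs["p_c"]
        rents = inputs["rents"]

        price_own = np.empty(n)
        carbon_now = np.empty(n)
        carbon_next = np.empty(n)
        vol_next = np.empty(n)
        vol_now = np.empty(n)
        rows = np.arange(n)
        npp_own = inputs["npp"][rows, type_idx]
        for j, t in enumerate(FOREST_TYPES):
            m = type_idx == j
            if not m.any():
                continue
            yc, cc = self.curves[t], self.carbon_curves[t]
            price_own[m] = inputs["prices"][j]
            vol_now[m] = yc(age[m]) * npp_own[m]
            vol_next[m] = yc(age[m] + 10.0) * npp_own[m]
            carbon_now[m] = cc(age[m]) * npp_own[m]
            carbon_next[m] = cc(age[m] + 10.0) * npp_own[m]

        tax_clear = p_c * scenario.release_fraction * carbon_now
        tax_partial = self.config.phi * tax_clear
        rev_growth = price_own * (vol_next - vol_now)
        if p_c > 0.0 and self.config.carbon_on_standing:
            rev_growth = rev_growth + p_c * (carbon_next - carbon_now)
        cov = {
            "clim": clim,
            "elev": self._elev,
            "volume": vol,
            "rents": rents,
            "viable": self._viable,
            "rev_clear": price_own * vol - tax_clear,
            "rev_partial": self.config.phi * price_own * vol - tax_partial,
            "rev_growth": rev_growth,
        }
        return cov, type_idx, age, vol, vol_next

    def step_decade(
        self,
        state: LandscapeState,
        scenario: Scenario,
        year: int,
        rng: np.random.Generator,
    ) -> LandscapeState:
        """Advance the landscape one decade from a decision at ``year``."""
        if year not in DECISION_YEARS:
            raise ValueError(f"decisions happen at {DECISION_YEARS}, not {year}")
        cov, type_idx, age, vol, vol_next = self._covariates(state, scenario, year)
        Vh, Vc, Vp, Vn = build_utilities(cov, self.params, self.config)
        fw = nested_forward(Vh, (Vc, Vp, Vn), self.params.lam_vec())
        J = joint_matrix(fw["P"], fw["Q"])
        cum = np.cumsum(J, axis=1)
        cum[:, -1] = 1.0
        u = rng.uniform(size=len(self.plots))
        alt = (u[:, None] > cum).sum(axis=1)

        new_type = type_idx.copy()
        new_age = age.copy()
        new_vol = vol.copy()
        for a, (k, j) in enumerate(self._labels):
            m = alt == a
            if not m.any():
                continue
            if k == "clearcut":
                assert cov["viable"][m, j].all(), "replant outside viable set"
                new_type[m] = j
                new_age[m] = 0.0
                new_vol[m] = 0.0
            elif k == "partialcut":
                new_vol[m] = (1.0 - self.config.phi) * vol[m]
            else:  # nocut
                if DISTURBANCE_OUTCOMES[j] == "grow":
                    new_age[m] = age[m] + 10.0
                    new_vol[m] = vol_next[m]
                else:  # fire / insects / disease: natural same-type regeneration
                    new_age[m] = 0.0
                    new_vol[m] = 0.0
        return LandscapeState(
            year + 10,
            pd.DataFrame(
                {
                    "plot_id": state.table["plot_id"].to_numpy(),
                    "forest_type": np.array(FOREST_TYPES)[new_type],
                    "stand_age": new_age,
                    "volume": new_vol,
                }
            ),
        )

    def run(
        self,
        scenario: Scenario,
        n_replicates: int = 1000,
        master_seed: int = 0,
        initial: LandscapeState | None = None,
    ) -> SimulationEnsemble:
        if n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        state0 = initial if initial is not None else initial_state(self.plots)
        n = len(self.plots)
        nd = len(REPORT_DECADES)
        types = np.empty((n_replicates, nd, n), np.int8)
        ages = np.empty((n_replicates, nd, n), np.float32)
        vols = np.empty((n_replicates, nd, n), np.float32)
        for r in range(n_replicates):
            rng = np.random.default_rng([master_seed, r])
            state = state0
            self._record(types, ages, vols, r, 0, state)
            for di, year in enumerate(DECISION_YEARS):
                state = self.step_decade(state, scenario, year, rng)
                self._record(types, ages, vols, r, di + 1, state)
        return SimulationEnsemble(
            scenario_name=scenario.name,
            master_seed=master_seed,
            plot_ids=self.plots["plot_id"].to_numpy(),
            decades=REPORT_DECADES,
            types=types,
            ages=ages,
            volumes=vols,
        )

    @staticmethod
    def _record(types, ages, vols, r, di, state: LandscapeState):
        types[r, di] = state.table["forest_type"].map(FOREST_TYPES.index).to_numpy()
        ages[r, di] = state.table["stand_age"].to_numpy()
        vols[r, di] = state.table["volume"].to_numpy()


# ---------------------------------------------------------------------------
# Functional wrappers and composition summaries


def step_decade(
    state: LandscapeState,
    scenario: Scenario,
    params: ChoiceParameters,
    year: int,
    rng: np.random.Generator,
    plots: pd.DataFrame,
    config: ChoiceConfig = ChoiceConfig(),
) -> LandscapeState:
    return LandscapeSimulator(plots, params, config).step_decade(
        state, scenario, year, rng
    )


def run_simulation(
    initial: LandscapeState,
    scenario: Scenario,
    params: ChoiceParameters,
    n_replicates: int,
    master_seed: int,
    plots: pd.DataFrame,
    config: ChoiceConfig = ChoiceConfig(),
) -> SimulationEnsemble:
    return LandscapeSimulator(plots, params, config).run(
        scenario, n_replicates, master_seed, initial
    )


def composition_series(ensemble: SimulationEnsemble) -> pd.DataFrame:
    """Per-decade, per-type mean proportion with across-replicate spread."""
    n_plots = ensemble.types.shape[2]
    rows = []
    for t in FOREST_TYPES:
        prop = ensemble.type_count(t) / n_plots  # (reps, decades)
        for di, d in enumerate(ensemble.decades):
            rows.append(
                {
                    "decade": d,
                    "forest_type": t,
                    "mean": prop[:, di].mean(),
                    "std": prop[:, di].std(ddof=0),
                }
            )
    return pd.DataFrame(rows)


def composition_difference(
    a: SimulationEnsemble, b: SimulationEnsemble
) -> pd.DataFrame:
    """Decade-wise difference of mean composition (a − b)."""
    if not np.array_equal(a.plot_ids, b.plot_ids) or a.decades != b.decades:
        raise ValueError("ensembles cover different plots or decades")
    ca = composition_series(a).set_index(["decade", "forest_type"])["mean"]
    cb = composition_series(b).set_index(["decade", "forest_type"])["mean"]
    return (ca - cb).rename("mean_diff").reset_index()
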