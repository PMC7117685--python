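"""Synthetic landscape, climate, species, and "true" parameter generators.

Everything downstream (choice model, estimation, simulation, habitat
accounting) is exercised on data produced here: an FIA-like plot table laid
on an abstract grid with a smooth west–east warm/dry climate gradient,
climate-change trajectories expressed as decadal additive deltas, species
profiles with contiguous ranges and binary forest-type associations, and a
sign-structured "true" coefficient set standing in for externally estimated
landowner preferences.

All generators are pure functions of their settings and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CLIMATE_VARS,
    FOREST_TYPES,
    ChoiceParameters,
    SpeciesProfile,
    viable_types_to_str,
)
from .economics import default_yield_curves

__all__ = [
    "ClimateGradient",
    "ClimateTrajectory",
    "generate_plots",
    "generate_climate_trajectory",
    "generate_species",
    "filter_species",
    "generate_true_parameters",
    "VIABILITY_ENVELOPES",
]

DECADES = tuple(range(2020, 2101, 10))


@dataclass(frozen=True)
class ClimateGradient:
    """West–east endpoints and noise scales of the synthetic climate field."""

    extent: float = 100.0     # grid size (unitless)
    t_west: float = 11.0      # °C growing-season mean at the wet/cool edge
    t_east: float = 20.0      # °C at the warm/dry edge
    p_west: float = 1150.0    # mm growing-season precipitation, wet edge
    p_east: float = 250.0     # mm, dry edge
    t_noise: float = 1.3      # °C iid noise on gs_tmean
    p_noise: float = 110.0    # mm iid noise on gs_precip


#: Rectangular climatic viability envelopes per forest type,
#: ((gs_tmean lo, hi) °C, (gs_precip lo, hi) mm).  A type is viable on a plot
#: when the plot's normals fall inside the envelope inflated by a tolerance.
VIABILITY_ENVELOPES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "DF": ((7.0, 17.5), (420.0, 2200.0)),
    "FSM": ((7.0, 15.0), (320.0, 2200.0)),
    "HSS": ((7.0, 16.0), (600.0, 2400.0)),
    "PP": ((13.0, 23.0), (80.0, 900.0)),
    "OSW": ((10.0, 22.0), (100.0, 1500.0)),
    "HW": ((10.5, 23.0), (120.0, 1700.0)),
}


def _envelope_viability(tmean, precip, tolerance_t=0.5, tolerance_p=50.0):
    """Boolean (n, 6) viability matrix from the rectangular envelopes."""
    n = len(tmean)
    out = np.zeros((n, len(FOREST_TYPES)), bool)
    for j, t in enumerate(FOREST_TYPES):
        (t_lo, t_hi), (p_lo, p_hi) = VIABILITY_ENVELOPES[t]
        out[:, j] = (
            (tmean >= t_lo - tolerance_t)
            & (tmean <= t_hi + tolerance_t)
            & (precip >= p_lo - tolerance_p)
            & (precip <= p_hi + tolerance_p)
        )
    return out


def _envelope_distance(tmean, precip):
    """(n, 6) distance of each plot's climate to each type's envelope (0 inside)."""
    n = len(tmean)
    d = np.zeros((n, len(FOREST_TYPES)))
    for j, t in enumerate(FOREST_TYPES):
        (t_lo, t_hi), (p_lo, p_hi) = VIABILITY_ENVELOPES[t]
        dt = np.maximum.reduce([t_lo - tmean, tmean - t_hi, np.zeros(n)])
        dp = np.maximum.reduce([p_lo - precip, precip - p_hi, np.zeros(n)])
        d[:, j] = np.hypot(dt, dp / 100.0)  # 100 mm ~ 1 °C for tie-breaking
    return d


def generate_plots(
    n_plots: int,
    n_ecoregions: int = 12,
    seed: int = 0,
    gradient: ClimateGradient = ClimateGradient(),
    plot_area_ha: float = 100.0,
) -> pd.DataFrame:
    """Generate an FIA-like plot table.

    Plots are scattered over a square grid partitioned into contiguous
    (nearest-centroid) ecoregions.  Climate normals follow the west–east
    warm/dry gradient plus iid noise; forest types are drawn with
    climate-dependent frequencies (cool/wet favours DF and hemlock/spruce,
    warm/dry favours ponderosa pine and hardwoods); the viable replant set
    comes from the climatic envelopes and always contains the current type
    plus at least one alternative.
    """
    if n_plots <= 0 or n_ecoregions <= 0:
        raise ValueError("n_plots and n_ecoregions must be positive")
    if n_plots < n_ecoregions:
        raise ValueError("need at least one plot per ecoregion")
    rng = np.random.default_rng(seed)
    ext = gradient.extent
    x = rng.uniform(0.0, ext, n_plots)
    y = rng.uniform(0.0, ext, n_plots)

    # Contiguous ecoregions: nearest of n_ecoregions random centroids.
    cx = rng.uniform(0.0, ext, n_ecoregions)
    cy = rng.uniform(0.0, ext, n_ecoregions)
    d2 = (x[:, None] - cx[None, :]) ** 2 + (y[:, None] - cy[None, :]) ** 2
    ecoregion = np.argmin(d2, axis=1)

    u = x / ext
    tmean = gradient.t_west + (gradient.t_east - gradient.t_west) * u
    tmean = tmean + rng.normal(0.0, gradient.t_noise, n_plots)
    precip = gradient.p_west + (gradient.p_east - gradient.p_west) * u
    precip = np.maximum(precip + rng.normal(0.0, gradient.p_noise, n_plots), 40.0)
    aug_tmax = tmean + 6.0 + np.abs(rng.normal(3.0, 1.6, n_plots))
    dec_tmin = tmean - 9.0 - np.abs(rng.normal(4.0, 2.2, n_plots))

    # Climate-dependent forest-type frequencies via a softmax over type scores.
    zt = (tmean - tmean.mean()) / max(tmean.std(), 1e-9)
    zp = (precip - precip.mean()) / max(precip.std(), 1e-9)
    score = {
        "DF": 1.0 - 0.6 * zt + 0.5 * zp,
        "FSM": -0.6 - 1.0 * zt + 0.1 * zp,
        "HSS": -0.1 - 0.4 * zt + 0.8 * zp,
        "PP": -0.3 + 0.8 * zt - 0.8 * zp,
        "OSW": -0.9 + 0.2 * zt - 0.2 * zp,
        "HW": 0.1 + 0.9 * zt - 0.3 * zp,
    }
    S = np.stack([score[t] for t in FOREST_TYPES], axis=1)
    S -= S.max(axis=1, keepdims=True)
    P = np.exp(S)
    P /= P.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    draws = rng.uniform(size=n_plots)
    type_idx = (draws[:, None] > cum).sum(axis=1)

    viable = _envelope_viability(tmean, precip)
    viable[np.arange(n_plots), type_idx] = True  # current type always viable
    # Guarantee >= 2 viable types: add the nearest-envelope alternative.
    dist = _envelope_distance(tmean, precip)
    only_one = viable.sum(axis=1) < 2
    if only_one.any():
        dist_masked = np.where(viable, np.inf, dist)
        nearest = np.argmin(dist_masked[only_one], axis=1)
        viable[np.flatnonzero(only_one), nearest] = True

    age = rng.uniform(5.0, 90.0, n_plots).round()
    curves = default_yield_curves()
    vol = np.empty(n_plots)
    for j, t in enumerate(FOREST_TYPES):
        m = type_idx == j
        vol[m] = curves[t](age[m]) * np.exp(rng.normal(0.0, 0.25, int(m.sum())))
    elev = 50.0 + 1900.0 * rng.beta(1.5, 3.0, n_plots)

    types = np.array(FOREST_TYPES)[type_idx]
    return pd.DataFrame(
        {
            "plot_id": np.arange(n_plots),
            "x": x,
            "y": y,
            "ecoregion_id": ecoregion,
            "forest_type": types,
            "stand_age": age,
            "volume": vol,
            "elevation": elev,
            "site_class": rng.integers(1, 6, n_plots),
            "gs_precip": precip,
            "gs_tmean": tmean,
            "aug_tmax": aug_tmax,
            "dec_tmin": dec_tmin,
            "viable_types": [
                viable_types_to_str(np.array(FOREST_TYPES)[row]) for row in viable
            ],
            "area": plot_area_ha,
        }
    )


@dataclass(frozen=True)
class ClimateTrajectory:
    """Per-decade additive deltas to the four climate normals.

    ``increments[i]`` is the delta added during the decade ending at
    ``decades[i]`` (ordered as CLIMATE_VARS); the cumulative delta in force
    at a decade is the sum of increments up to and including it.  Deltas
    apply uniformly across ecoregions.
    """

    decades: tuple[int, ...]
    increments: np.ndarray  # (n_decades, 4)

    def cumulative(self, decade: int) -> np.ndarray:
        """Cumulative delta vector (ordered as CLIMATE_VARS) at ``decade``."""
        mask = np.array(self.decades) <= decade
        return self.increments[mask].sum(axis=0)

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.increments == 0.0))


def generate_climate_trajectory(
    scenario_kind: str,
    horizon_decades: int = 8,
    warming_total: float = 4.0,
    drying_total: float = 80.0,
) -> ClimateTrajectory:
    """Baseline (all-zero) or linear warming/drying decadal trajectory.

    Under ``warming`` the three temperature normals rise by equal per-decade
    increments summing to ``warming_total`` °C by 2100, and growing-season
    precipitation falls linearly by ``drying_total`` mm in total.
    """
    if horizon_decades < 0:
        raise ValueError("horizon_decades must be nonnegative")
    decades = tuple(d for d in DECADES if d > 2020)[:horizon_decades]
    n = len(decades)
    inc = np.zeros((n, len(CLIMATE_VARS)))
    if scenario_kind == "warming" and n > 0:
        inc[:, CLIMATE_VARS.index("gs_precip")] = -drying_total / n
        for var in ("gs_tmean", "aug_tmax", "dec_tmin"):
            inc[:, CLIMATE_VARS.index(var)] = warming_total / n
    elif scenario_kind not in ("baseline", "warming"):
        raise ValueError(f"unknown scenario_kind {scenario_kind!r}")
    return ClimateTrajectory(decades, inc)


#: Per-taxon probability that a species uses each forest type; amphibians are
#: biased toward wet conifer forests, birds are the least specialised.
_USE_TEMPLATES = {
    "amphibian": {"DF": 0.92, "FSM": 0.55, "HSS": 0.85, "PP": 0.12, "OSW": 0.35, "HW": 0.30},
    "bird": {"DF": 0.62, "FSM": 0.50, "HSS": 0.55, "PP": 0.50, "OSW": 0.50, "HW": 0.52},
    "mammal": {"DF": 0.72, "FSM": 0.60, "HSS": 0.60, "PP": 0.45, "OSW": 0.50, "HW": 0.40},
}


def generate_species(
    n_amphibians: int = 8,
    n_birds: int = 12,
    n_mammals: int = 15,
    plots: pd.DataFrame | None = None,
    seed: int = 0,
    p_old_growth: float = 0.15,
    p_forest_associated: float = 0.9,
) -> list[SpeciesProfile]:
    """Generate candidate species profiles with contiguous ranges.

    Each range is the set of plots nearest to a random centroid plot (an L2
    ball in grid coordinates) with a per-species size drawn broadly enough
    that some candidates fail the >500-plot range criterion; associations are
    drawn from taxon templates, and old-growth-specialist /
    non-forest-associated flags are set with small probability so the filter
    has work to do.
    """
    if plots is None or len(plots) == 0:
        raise ValueError("plots table must be nonempty")
    if n_amphibians + n_birds + n_mammals <= 0:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    xy = plots[["x", "y"]].to_numpy()
    ids = plots["plot_id"].to_numpy()
    n = len(plots)
    out: list[SpeciesProfile] = []
    counter = 0
    for taxon, count in (
        ("amphibian", n_amphibians),
        ("bird", n_birds),
        ("mammal", n_mammals),
    ):
        tmpl = _USE_TEMPLATES[taxon]
        for _ in range(count):
            counter += 1
            centroid = xy[rng.integers(n)]
            size = int(np.clip(round(n * rng.beta(1.5, 2.2)), 30, n))
            order = np.argsort(np.hypot(*(xy - centroid).T), kind="stable")
            range_ids = frozenset(int(i) for i in ids[order[:size]])
            uses = {t: int(rng.uniform() < tmpl[t]) for t in FOREST_TYPES}
            out.append(
                SpeciesProfile(
                    species_id=f"sp{counter:03d}",
                    common_name=f"{taxon} {counter}",
                    taxon=taxon,
                    range_plots=range_ids,
                    uses=uses,
                    old_growth_specialist=bool(rng.uniform() < p_old_growth),
                    forest_associated=bool(rng.uniform() < p_forest_associated),
                )
            )
    return out


def filter_species(
    candidates: list[SpeciesProfile],
    plots: pd.DataFrame,
    min_range_plots: int = 500,
) -> list[SpeciesProfile]:
    """Apply the four habitat-specialist selection criteria.

    Retains species that are (1) forest associated, (2) not a forest
    generalist (associations not all-1; all-0 likewise excluded), (3) not
    extremely range limited (strictly more than ``min_range_plots`` plots in
    range), and (4) not an old-growth specialist.  Idempotent.
    """
    plot_ids = set(int(i) for i in plots["plot_id"])
    kept = []
    for sp in candidates:
        uses = sp.uses_array()
        if not sp.forest_associated:
            continue
        if uses.all() or not uses.any():
            continue
        if len(sp.range_plots & plot_ids) <= min_range_plots:
            continue
        if sp.old_growth_specialist:
            continue
        kept.append(sp)
    return kept


def generate_true_parameters(seed: int = 0) -> ChoiceParameters:
    """Draw a sign-structured "true" coefficient set.

    The draws stand in for externally estimated landowner preferences and
    respect three structural requirements: warmer/drier climates lower
    Douglas-fir replant utility relative to hardwoods (hardwood and pine
    temperature slopes positive against the DF reference, precipitation
    slopes negative), the rent slope is positive, and every inclusive-value
    coefficient lies in [0.3, 1.0].
    """
    rng = np.random.default_rng(seed)
    p = ChoiceParameters()
    p.alpha_clear0 = rng.uniform(-4.8, -4.2)
    p.alpha_partial0 = rng.uniform(-5.6, -5.0)
    p.alpha_rev = rng.uniform(4e-5, 7e-5)
    p.alpha_grow = rng.uniform(1.0e-4, 2.0e-4)
    p.beta_rent = rng.uniform(0.008, 0.012)

    # climate slope order: (gs_precip, gs_tmean, aug_tmax, dec_tmin)
    clim_ranges = {
        "FSM": ((0.0, 0.0015), (-0.30, -0.10), (-0.03, 0.0), (0.0, 0.03)),
        "HSS": ((0.0008, 0.0025), (-0.20, -0.02), (-0.03, 0.0), (0.0, 0.03)),
        "PP": ((-0.0035, -0.0012), (0.10, 0.28), (0.0, 0.04), (-0.02, 0.02)),
        "OSW": ((-0.0018, -0.0002), (0.02, 0.15), (0.0, 0.03), (-0.02, 0.02)),
        "HW": ((-0.0035, -0.0012), (0.25, 0.40), (0.0, 0.05), (0.0, 0.04)),
    }
    # Anchor non-reference intercepts at a cool/wet reference climate so the
    # climate slopes act on departures from it: at the reference, each type's
    # utility sits base_j below Douglas-fir (before rent differences), and
    # warming/drying moves the margin toward hardwoods and pine.
    clim_ref = np.array([900.0, 13.0, 22.0, 2.0])
    elev_ref = 400.0
    base_range = {
        "FSM": (-2.6, -1.6),
        "HSS": (-2.0, -1.0),
        "PP": (-2.6, -1.6),
        "OSW": (-3.0, -2.0),
        "HW": (-1.6, -0.6),
    }
    for t in FOREST_TYPES:
        if t == "DF":
            continue
        lo_hi = clim_ranges[t]
        p.beta_climate[t] = np.array([rng.uniform(lo, hi) for lo, hi in lo_hi])
        p.beta_elev[t] = rng.uniform(-4e-4, 4e-4)
        base = rng.uniform(*base_range[t])
        p.beta_intercept[t] = float(
            base - p.beta_climate[t] @ clim_ref - p.beta_elev[t] * elev_ref
        )

    p.lam = {k: float(rng.uniform(0.5, 0.9)) for k in ("clearcut", "partialcut", "nocut")}

    # gamma order: (intercept, volume, gs_precip, gs_tmean, aug_tmax, dec_tmin, elev)
    p.gamma["fire"] = np.array(
        [
            rng.uniform(-3.3, -2.9),
            rng.uniform(0.0, 4e-4),
            rng.uniform(-8e-4, -3e-4),
            0.0,
            rng.uniform(0.04, 0.09),  # hotter Augusts raise fire odds
            0.0,
            rng.uniform(0.0, 1e-4),
        ]
    )
    p.gamma["insects"] = np.array(
        [
            rng.uniform(-3.6, -3.1),
            rng.uniform(5e-4, 1.2e-3),
            rng.uniform(-3e-4, 0.0),
            rng.uniform(0.02, 0.06),
            0.0,
            rng.uniform(0.0, 0.03),
            0.0,
        ]
    )
    p.gamma["disease"] = np.array(
        [
            rng.uniform(-3.9, -3.3),
            rng.uniform(0.0, 6e-4),
            rng.uniform(1e-4, 5e-4),
            rng.uniform(0.0, 0.03),
            0.0,
            0.0,
            rng.uniform(-1e-4, 1e-4),
        ]
    )
    p.validate()
    return p
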