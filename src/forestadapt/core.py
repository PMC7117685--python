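"""Shared domain types and constants.

The landscape is described at the level of inventory plots, each carrying one
of six forest-type groups (the FIA groupings used across the US Pacific
states): Douglas-fir (DF), fir/spruce/mountain-hemlock (FSM),
hemlock/sitka-spruce (HSS), ponderosa pine (PP), other softwoods (OSW) and
hardwoods (HW).  Landowners face a two-level decision each decade: a harvest
choice (clear-cut, partial-cut, or no cut) and, conditional on that choice, a
sub-nest outcome (which forest type to replant after a cut; which natural
fate — growth, fire, insects, disease — befalls an uncut stand).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

FOREST_TYPES: tuple[str, ...] = ("DF", "FSM", "HSS", "PP", "OSW", "HW")
HARVEST_OPTIONS: tuple[str, ...] = ("clearcut", "partialcut", "nocut")
DISTURBANCE_OUTCOMES: tuple[str, ...] = ("grow", "fire", "insects", "disease")
CLIMATE_VARS: tuple[str, ...] = ("gs_precip", "gs_tmean", "aug_tmax", "dec_tmin")

#: Reference categories whose coefficients are fixed to zero for identification.
REFERENCE_FOREST_TYPE = "DF"
REFERENCE_DISTURBANCE = "grow"

TYPE_INDEX = {t: i for i, t in enumerate(FOREST_TYPES)}
HARVEST_INDEX = {k: i for i, k in enumerate(HARVEST_OPTIONS)}
DISTURBANCE_INDEX = {d: i for i, d in enumerate(DISTURBANCE_OUTCOMES)}


@dataclass(frozen=True)
class ClimateNormals:
    """30-year climate normals at a plot.

    gs_* aggregates are taken over the growing season (months with mean
    temperature above 10 °C).
    """

    gs_precip: float  # mm, growing-season total precipitation
    gs_tmean: float   # °C, growing-season mean temperature
    aug_tmax: float   # °C, August maximum temperature
    dec_tmin: float   # °C, December minimum temperature

    def __post_init__(self) -> None:
        if not (self.aug_tmax >= self.gs_tmean >= self.dec_tmin):
            raise ValueError(
                "climate normals must satisfy aug_tmax >= gs_tmean >= dec_tmin"
            )
        if self.gs_precip < 0:
            raise ValueError("gs_precip must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.gs_precip, self.gs_tmean, self.aug_tmax, self.dec_tmin], float
        )


@dataclass(frozen=True)
class SpeciesProfile:
    """A habitat-specialist vertebrate with a range and forest-type associations.

    ``uses`` maps each of the six forest types to 0/1: whether plots of that
    type count as potential (breeding) habitat for the species.
    """

    species_id: str
    common_name: str
    taxon: str  # amphibian | bird | mammal
    range_plots: frozenset[int]
    uses: Mapping[str, int]
    old_growth_specialist: bool = False
    forest_associated: bool = True

    def __post_init__(self) -> None:
        if self.taxon not in ("amphibian", "bird", "mammal"):
            raise ValueError(f"unknown taxon {self.taxon!r}")
        if set(self.uses) != set(FOREST_TYPES):
            raise ValueError("uses must have exactly one entry per forest type")

    def uses_array(self) -> np.ndarray:
        return np.array([self.uses[t] for t in FOREST_TYPES], dtype=bool)


@dataclass(frozen=True)
class ChoiceConfig:
    """Structural switches of the choice model that are not coefficients.

    phi
        Partial-cut removal fraction: share of standing volume removed by a
        partial cut (and the scaling applied to the harvest carbon tax of a
        partial cut).
    partial_replant
        If True, a partial cut opens the same replant sub-nest as a clear
        cut; if False (default), a partial cut keeps the current forest type
        and its sub-nest is the degenerate {keep} outcome.
    carbon_on_standing
        If True, the no-cut "growth revenue" term also accrues the value of
        carbon sequestered by the standing stand over the coming decade.
    """

    phi: float = 0.4
    partial_replant: bool = False
    carbon_on_standing: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must be in (0, 1)")


@dataclass
class ChoiceParameters:
    """All coefficients of the nested-logit land-value functions.

    Harvest level (``alpha``): intercepts for clear-cut and partial-cut
    (no-cut intercept fixed at 0), a shared slope on net harvest revenue, and
    a slope on the growth of harvest revenue for uncut stands.

    Replant level (``beta``): per-forest-type intercepts (reference type DF
    fixed at 0), one shared slope on the effective (carbon-augmented) annual
    rent, per-type slopes on the four climate normals, and a per-type slope
    on elevation.

    Nest level (``lam``): inclusive-value coefficients per harvest option,
    each in (0, 1].

    Disturbance level (``gamma``): multinomial-logit coefficients per outcome
    — (intercept, volume, 4 climate normals, elevation) — with the "grow"
    outcome fixed at zero utility.
    """

    alpha_clear0: float = 0.0
    alpha_partial0: float = 0.0
    alpha_rev: float = 0.0
    alpha_grow: float = 0.0
    beta_rent: float = 0.0
    beta_intercept: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in FOREST_TYPES}
    )
    beta_climate: dict[str, np.ndarray] = field(
        default_factory=lambda: {t: np.zeros(4) for t in FOREST_TYPES}
    )
    beta_elev: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in FOREST_TYPES}
    )
    lam: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in HARVEST_OPTIONS}
    )
    gamma: dict[str, np.ndarray] = field(
        default_factory=lambda: {d: np.zeros(7) for d in DISTURBANCE_OUTCOMES}
    )

    def validate(self) -> None:
        for k in HARVEST_OPTIONS:
            if not 0.0 < self.lam[k] <= 1.0:
                raise ValueError(f"lambda[{k}]={self.lam[k]} outside (0, 1]")
        ref = REFERENCE_FOREST_TYPE
        if self.beta_intercept[ref] != 0.0 or self.beta_elev[ref] != 0.0:
            raise ValueError(f"reference type {ref} coefficients must be 0")
        if np.any(self.beta_climate[ref] != 0.0):
            raise ValueError(f"reference type {ref} climate slopes must be 0")
        if np.any(self.gamma[REFERENCE_DISTURBANCE] != 0.0):
            raise ValueError("reference disturbance outcome must have zero coefficients")

    # -- array views used by the vectorized likelihood/simulator ------------

    def beta_intercept_vec(self) -> np.ndarray:
        return np.array([self.beta_intercept[t] for t in FOREST_TYPES])

    def beta_climate_mat(self) -> np.ndarray:
        return np.stack([np.asarray(self.beta_climate[t], float) for t in FOREST_TYPES])

    def beta_elev_vec(self) -> np.ndarray:
        return np.array([self.beta_elev[t] for t in FOREST_TYPES])

    def lam_vec(self) -> np.ndarray:
        return np.array([self.lam[k] for k in HARVEST_OPTIONS])

    def gamma_mat(self) -> np.ndarray:
        return np.stack([np.asarray(self.gamma[d], float) for d in DISTURBANCE_OUTCOMES])

    def copy(self) -> "ChoiceParameters":
        return replace(
            self,
            beta_intercept=dict(self.beta_intercept),
            beta_climate={t: np.array(v) for t, v in self.beta_climate.items()},
            beta_elev=dict(self.beta_elev),
            lam=dict(self.lam),
            gamma={d: np.array(v) for d, v in self.gamma.items()},
        )


def viable_types_to_str(types) -> str:
    """Encode a viable-type set as a '|'-joined string (canonical order)."""
    return "|".join(t for t in FOREST_TYPES if t in set(types))


def viable_types_from_str(s: str) -> tuple[str, ...]:
    return tuple(t for t in s.split("|") if t)
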