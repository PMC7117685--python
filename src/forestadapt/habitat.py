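"""Wildlife potential-habitat accounting over simulation ensembles.

Potential habitat for a species is the set of plots inside its range whose
current forest type the species is associated with (binary association,
irrespective of occupancy).  Ensembles of simulated landscapes are converted
into per-decade suitable-plot counts — over the whole range and within each
ecoregion holding at least 50 in-range plots — then into percent changes
versus the baseline scenario, tail-based projection intervals ranked by
landscape-wide Douglas-fir change, sign/threshold classifications, and
marginal decadal habitat areas summed over species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpeciesProfile
from .simulation import LandscapeState, SimulationEnsemble

__all__ = [
    "HabitatSeries",
    "ChangeSummary",
    "suitable_count",
    "habitat_series",
    "percent_change_vs_baseline",
    "df_tail_intervals",
    "summarize_change",
    "classify_changes",
    "marginal_habitat_area",
]


@dataclass
class HabitatSeries:
    """Per-replicate, per-decade suitable-plot counts for one species and scope."""

    species_id: str
    scope: str  # "range" or "eco:<id>"
    decades: tuple[int, ...]
    counts: np.ndarray  # (n_replicates, n_decades)

    @property
    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        return self.counts.std(axis=0, ddof=0)

    def mean_at(self, decade: int) -> float:
        return float(self.mean[self.decades.index(decade)])


@dataclass
class ChangeSummary:
    """Percent change in potential habitat through 2100 versus baseline."""

    species_id: str
    scope: str
    mean_pct: float
    classification: str  # positive | negative | positive>5% | negative>5% | nonsignificant
    high_tail_pct: float | None = None  # mean over most-DF-losing replicates
    low_tail_pct: float | None = None


def suitable_count(
    state: LandscapeState,
    species: SpeciesProfile,
    scope: str = "range",
    plots: pd.DataFrame | None = None,
) -> int:
    """Number of in-scope, in-range plots whose forest type the species uses.

    ``scope`` is "range" or "eco:<id>"; the latter needs the plot table for
    ecoregion membership.
    """
    tab = state.table
    in_range = tab["plot_id"].isin(species.range_plots).to_numpy()
    if scope != "range":
        if plots is None:
            raise ValueError("ecoregion scope requires the plot table")
        eco = int(scope.split(":", 1)[1])
        if eco not in set(int(e) for e in plots["ecoregion_id"].unique()):
            raise ValueError(f"unknown ecoregion {eco}")
        eco_of = dict(zip(plots["plot_id"], plots["ecoregion_id"]))
        in_scope = np.array([eco_of[int(p)] == eco for p in tab["plot_id"]])
        in_range = in_range & in_scope
    used = tab["forest_type"].map(species.uses).to_numpy(bool)
    return int((in_range & used).sum())


def habitat_series(
    ensemble: SimulationEnsemble,
    species: SpeciesProfile,
    plots: pd.DataFrame,
    min_ecoregion_plots: int = 50,
) -> list[HabitatSeries]:
    """One whole-range series plus one per qualifying ecoregion.

    An ecoregion qualifies when at least ``min_ecoregion_plots`` of the
    species' range plots fall inside it (inclusive threshold).
    """
    ids = ensemble.plot_ids
    in_range = np.isin(ids, list(species.range_plots))
    uses = species.uses_array()
    suitable = uses[ensemble.types] & in_range[None, None, :]
    out = [
        HabitatSeries(
            species.species_id, "range", ensemble.decades, suitable.sum(axis=2)
        )
    ]
    eco_of = (
        plots.set_index("plot_id")["ecoregion_id"].reindex(ids).to_numpy()
    )
    for eco in np.unique(eco_of):
        m = in_range & (eco_of == eco)
        if m.sum() >= min_ecoregion_plots:
            counts = (suitable & m[None, None, :]).sum(axis=2)
            out.append(
                HabitatSeries(
                    species.species_id, f"eco:{int(eco)}", ensemble.decades, counts
                )
            )
    return out


def percent_change_vs_baseline(
    series: HabitatSeries, baseline: HabitatSeries, decade: int = 2100
) -> float:
    """Percent change of mean suitable-plot count at ``decade`` versus baseline.

    Returns NaN (flagged undefined) when the baseline mean is zero.
    """
    if series.species_id != baseline.species_id or series.scope != baseline.scope:
        raise ValueError("series compare different species or scopes")
    if series.decades != baseline.decades:
        raise ValueError("series cover different decades")
    b = baseline.mean_at(decade)
    if b == 0.0:
        return float("nan")
    return 100.0 * (series.mean_at(decade) - b) / b


def df_tail_intervals(
    df_changes: np.ndarray,
    metric: np.ndarray,
    n_tail: int = 100,
) -> tuple[float, float, float]:
    """Projection interval from the Douglas-fir-change tails of an ensemble.

    Replicates are ordered from greatest Douglas-fir loss to greatest gain
    (ties broken by replicate index); returns the species-metric mean over
    the ``n_tail`` most-DF-losing replicates, over all replicates, and over
    the ``n_tail`` least-DF-losing replicates.
    """
    df_changes = np.asarray(df_changes, float)
    metric = np.asarray(metric, float)
    if df_changes.shape != metric.shape:
        raise ValueError("df_changes and metric must align per replicate")
    n = len(df_changes)
    if not 1 <= n_tail <= n // 2:
        raise ValueError("n_tail must be between 1 and n_replicates/2")
    order = np.lexsort((np.arange(n), df_changes))  # ascending: most loss first
    high = float(metric[order[:n_tail]].mean())
    low = float(metric[order[-n_tail:]].mean())
    return high, float(metric.mean()), low


def summarize_change(
    series: HabitatSeries,
    baseline: HabitatSeries,
    df_changes: np.ndarray | None = None,
    n_tail: int | None = None,
    threshold_pct: float = 5.0,
    decade: int = 2100,
) -> ChangeSummary:
    """Build a ChangeSummary with the 5 % rule and a replicate-interval ns test.

    A change is nonsignificant when the across-replicate (paired, common
    random numbers) 95 % interval of the count difference covers zero.
    """
    mean_pct = percent_change_vs_baseline(series, baseline, decade)
    di = series.decades.index(decade)
    diffs = series.counts[:, di].astype(float) - baseline.counts[:, di].astype(float)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    if np.isnan(mean_pct) or lo <= 0.0 <= hi:
        cls = "nonsignificant"
    elif mean_pct > 0:
        cls = "positive>5%" if mean_pct > threshold_pct else "positive"
    else:
        cls = "negative>5%" if mean_pct < -threshold_pct else "negative"
    high = low = None
    if df_changes is not None and n_tail is not None:
        b = baseline.mean_at(decade)
        if b != 0.0:
            h, _, l = df_tail_intervals(
                df_changes, 100.0 * (series.counts[:, di] - b) / b, n_tail
            )
            high, low = h, l
    return ChangeSummary(series.species_id, series.scope, mean_pct, cls, high, low)


def classify_changes(changes, threshold_pct: float = 5.0) -> dict[str, int]:
    """Tally sign and >threshold counts over percent changes.

    ``changes`` may be ChangeSummary objects or raw percent values; zero and
    NaN changes fall in neither sign bin.  Tallies are order-invariant.
    """
    vals = [
        c.mean_pct if isinstance(c, ChangeSummary) else float(c) for c in changes
    ]
    out = {"positive": 0, "negative": 0, "gt_positive": 0, "gt_negative": 0}
    for v in vals:
        if np.isnan(v) or v == 0.0:
            continue
        if v > 0:
            out["positive"] += 1
            if v > threshold_pct:
                out["gt_positive"] += 1
        else:
            out["negative"] += 1
            if v < -threshold_pct:
                out["gt_negative"] += 1
    return out


def marginal_habitat_area(
    scenario_series: dict[str, HabitatSeries],
    baseline_series: dict[str, HabitatSeries],
    plot_area_ha: float = 100.0,
) -> pd.DataFrame:
    """Per-decade total habitat area lost and gained across species (km²).

    For each decade d ≥ 2030, each species contributes the change versus
    baseline of its suitable area at d minus the same at d−10; negative
    contributions are summed (in magnitude) into "lost", positive ones into
    "gained".  Summing (gained − lost) across decades telescopes to the
    cumulative end-of-horizon difference.
    """
    if set(scenario_series) != set(baseline_series):
        raise ValueError("species sets differ between scenario and baseline")
    if not scenario_series:
        return pd.DataFrame(columns=["decade", "lost_km2", "gained_km2"])
    first = next(iter(scenario_series.values()))
    decades = first.decades
    rows = []
    for d_prev, d in zip(decades[:-1], decades[1:]):
        lost = gained = 0.0
        for sid, s in scenario_series.items():
            b = baseline_series[sid]
            if s.decades != decades or b.decades != decades:
                raise ValueError("mismatched decades across series")
            diff_now = s.mean_at(d) - b.mean_at(d)
            diff_prev = s.mean_at(d_prev) - b.mean_at(d_prev)
            marginal_km2 = (diff_now - diff_prev) * plot_area_ha / 100.0
            if marginal_km2 < 0:
                lost += -marginal_km2
            else:
                gained += marginal_km2
        rows.append({"decade": d, "lost_km2": lost, "gained_km2": gained})
    return pd.DataFrame(rows)
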