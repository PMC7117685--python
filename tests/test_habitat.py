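"""Habitat accounting: counts, percent changes, tails, tallies, marginal areas."""

import numpy as np
import pandas as pd
import pytest

import forestadapt as fa


def make_state(types, plot_ids=None, decade=2020):
    n = len(types)
    return fa.LandscapeState(
        decade,
        pd.DataFrame(
            {
                "plot_id": plot_ids if plot_ids is not None else np.arange(n),
                "forest_type": types,
                "stand_age": np.zeros(n),
                "volume": np.zeros(n),
            }
        ),
    )


def make_species(uses_types, range_ids, sid="s1"):
    return fa.SpeciesProfile(
        species_id=sid,
        common_name=sid,
        taxon="mammal",
        range_plots=frozenset(range_ids),
        uses={t: int(t in uses_types) for t in fa.FOREST_TYPES},
    )


def make_ensemble(types_rdn, plot_ids=None, decades=None):
    """Build a SimulationEnsemble directly from a (reps, decades, plots) type array."""
    types_rdn = np.asarray(types_rdn, np.int8)
    r, d, n = types_rdn.shape
    return fa.SimulationEnsemble(
        scenario_name="synthetic",
        master_seed=0,
        plot_ids=np.arange(n) if plot_ids is None else np.asarray(plot_ids),
        decades=tuple(range(2020, 2020 + 10 * d, 10)) if decades is None else decades,
        types=types_rdn,
        ages=np.zeros_like(types_rdn, np.float32),
        volumes=np.zeros_like(types_rdn, np.float32),
    )


class TestSuitableCount:
    def test_hand_count(self):
        state = make_state(["DF", "DF", "HW", "PP", "HSS"])
        sp = make_species({"DF", "HSS"}, range(5))
        assert fa.suitable_count(state, sp) == 3

    def test_all_zero_uses(self):
        state = make_state(["DF", "HW"])
        sp = make_species(set(), range(2))
        assert fa.suitable_count(state, sp) == 0

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            types = [fa.FOREST_TYPES[i] for i in rng.integers(0, 6, n)]
            ids = rng.choice(10 * n, size=n, replace=False)
            state = make_state(types, plot_ids=ids)
            range_ids = set(
                int(i) for i in rng.choice(ids, size=rng.integers(1, n + 1), replace=False)
            )
            used = set(
                fa.FOREST_TYPES[i]
                for i in rng.choice(6, size=rng.integers(0, 7), replace=False)
            )
            sp = make_species(used, range_ids)
            oracle = sum(
                1
                for pid, t in zip(ids, types)
                if int(pid) in range_ids and t in used
            )
            assert fa.suitable_count(state, sp) == oracle

    def test_ecoregion_scope(self, plots_small):
        state = fa.initial_state(plots_small)
        sp = make_species({"DF"}, plots_small.plot_id)
        eco = int(plots_small.ecoregion_id.iloc[0])
        by_eco = fa.suitable_count(state, sp, f"eco:{eco}", plots_small)
        whole = fa.suitable_count(state, sp)
        assert 0 <= by_eco <= whole
        with pytest.raises(ValueError):
            fa.suitable_count(state, sp, "eco:9999", plots_small)


class TestHabitatSeries:
    def _plots(self, eco_sizes):
        rows = []
        pid = 0
        for eco, size in enumerate(eco_sizes):
            for _ in range(size):
                rows.append({"plot_id": pid, "ecoregion_id": eco})
                pid += 1
        df = pd.DataFrame(rows)
        df["forest_type"] = "DF"
        return df

    def test_ecoregion_threshold_inclusive(self):
        plots = self._plots([49, 50, 30])
        n = len(plots)
        ens = make_ensemble(np.zeros((2, 3, n)))  # all DF
        sp = make_species({"DF"}, range(n))
        series = fa.habitat_series(ens, sp, plots, min_ecoregion_plots=50)
        scopes = {h.scope for h in series}
        assert scopes == {"range", "eco:1"}

    def test_single_replicate_means(self):
        plots = self._plots([60])
        ens = make_ensemble(np.zeros((1, 2, 60)))
        sp = make_species({"DF"}, range(60))
        h = fa.habitat_series(ens, sp, plots)[0]
        assert np.array_equal(h.mean, h.counts[0])

    def test_ecoregion_sums_bounded_by_range(self, plots_small, true_params):
        sim = fa.LandscapeSimulator(plots_small, true_params)
        ens = sim.run(fa.make_scenario("baseline", plots_small), 2, 1)
        sp = make_species({"DF", "HSS"}, plots_small.plot_id)
        series = fa.habitat_series(ens, sp, plots_small)
        whole = next(h for h in series if h.scope == "range")
        ecos = [h for h in series if h.scope != "range"]
        eco_sum = sum(h.mean for h in ecos)
        assert np.all(eco_sum <= whole.mean + 1e-9)


class TestPercentChange:
    def _series(self, means, sid="s1", scope="range"):
        counts = np.asarray(means, float)[None, :]
        decades = tuple(range(2020, 2020 + 10 * counts.shape[1], 10))
        return fa.HabitatSeries(sid, scope, decades, counts)

    def test_identity_and_arithmetic(self):
        decs = 9
        b = self._series([100.0] * decs)
        assert fa.percent_change_vs_baseline(b, b) == 0.0
        s = self._series([100.0] * (decs - 1) + [80.0])
        assert fa.percent_change_vs_baseline(s, b) == pytest.approx(-20.0)

    def test_zero_baseline_flagged(self):
        b = self._series([0.0] * 9)
        s = self._series([5.0] * 9)
        assert np.isnan(fa.percent_change_vs_baseline(s, b))

    def test_scope_mismatch_rejected(self):
        b = self._series([1.0] * 9, scope="range")
        s = self._series([1.0] * 9, scope="eco:1")
        with pytest.raises(ValueError):
            fa.percent_change_vs_baseline(s, b)


class TestTailIntervals:
    def test_hand_case(self):
        df_changes = np.arange(-10.0, 0.0)  # -10 ... -1
        high, mean, low = fa.df_tail_intervals(df_changes, df_changes, n_tail=2)
        assert (high, mean, low) == (-9.5, -5.5, -1.5)

    def test_partition_identity(self):
        rng = np.random.default_rng(1)
        df_changes = rng.normal(size=40)
        metric = rng.normal(size=40)
        high, mean, low = fa.df_tail_intervals(df_changes, metric, n_tail=20)
        assert (high + low) / 2 == pytest.approx(mean, abs=1e-12)

    def test_independent_metric_tails_agree(self):
        rng = np.random.default_rng(2)
        n, n_tail = 2000, 200
        df_changes = rng.normal(size=n)
        metric = rng.normal(size=n)  # independent of the ordering variable
        high, mean, low = fa.df_tail_intervals(df_changes, metric, n_tail)
        se = metric.std() / np.sqrt(n_tail)
        assert abs(high - mean) < 4 * se
        assert abs(low - mean) < 4 * se

    def test_n_tail_bounds(self):
        with pytest.raises(ValueError):
            fa.df_tail_intervals(np.zeros(10), np.zeros(10), 6)


class TestClassify:
    def test_hand_tally(self):
        got = fa.classify_changes([+2.0, -7.0, -3.0, 0.0], threshold_pct=5)
        assert got == {
            "positive": 1, "negative": 2, "gt_positive": 0, "gt_negative": 1,
        }

    def test_all_zero(self):
        got = fa.classify_changes([0.0, 0.0])
        assert all(v == 0 for v in got.values())

    def test_order_invariant(self):
        vals = [3.0, -8.0, 6.0, -1.0, 0.0, float("nan")]
        assert fa.classify_changes(vals) == fa.classify_changes(vals[::-1])


class TestMarginalArea:
    def _series(self, means, sid):
        counts = np.asarray(means, float)[None, :]
        decades = tuple(range(2020, 2020 + 10 * counts.shape[1], 10))
        return fa.HabitatSeries(sid, "range", decades, counts)

    def test_identity_when_equal(self):
        s = {"a": self._series([50, 50, 50], "a")}
        out = fa.marginal_habitat_area(s, s)
        assert (out.lost_km2 == 0).all() and (out.gained_km2 == 0).all()

    def test_constant_loss(self):
        base = {"a": self._series([100] * 9, "a")}
        scen = {"a": self._series([100 - 10 * i for i in range(9)], "a")}
        out = fa.marginal_habitat_area(scen, base, plot_area_ha=100.0)
        assert np.allclose(out.lost_km2, 10.0)
        assert np.allclose(out.gained_km2, 0.0)

    def test_telescoping_identity(self):
        rng = np.random.default_rng(3)
        base, scen = {}, {}
        for i in range(10):
            sid = f"s{i}"
            base[sid] = self._series(rng.uniform(50, 150, 9), sid)
            scen[sid] = self._series(rng.uniform(50, 150, 9), sid)
        out = fa.marginal_habitat_area(scen, base)
        net = (out.gained_km2 - out.lost_km2).sum()
        cum = sum(
            (scen[s].mean_at(2100) - base[s].mean_at(2100))
            - (scen[s].mean_at(2020) - base[s].mean_at(2020))
            for s in scen
        )
        assert net == pytest.approx(cum * 100.0 / 100.0, abs=1e-9)

    def test_species_mismatch_rejected(self):
        a = {"a": self._series([1] * 9, "a")}
        b = {"b": self._series([1] * 9, "b")}
        with pytest.raises(ValueError):
            fa.marginal_habitat_area(a, b)
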