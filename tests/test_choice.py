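"""Nested-logit probability layers: closed forms, normalization, sampling."""

import numpy as np
import pytest
from scipy import stats

import forestadapt as fa

from conftest import random_context


def flat_composite_probs(Vh, sub, lambdas=None):
    """Oracle: single-level multinomial logit over (k, j) composites (λ = 1)."""
    labels, utils = [], []
    for k in fa.HARVEST_OPTIONS:
        for j, v in sub[k].items():
            labels.append((k, j))
            utils.append(Vh[k] + v)
    u = np.array(utils)
    p = np.exp(u - u.max())
    p /= p.sum()
    return dict(zip(labels, p))


class TestInclusiveValue:
    def test_closed_forms(self):
        assert fa.inclusive_value([0.0, 1.0], 1.0) == pytest.approx(
            np.log(1 + np.e), abs=1e-12
        )
        # constant vector: c/lambda + log m
        for c, lam, m in [(2.0, 0.5, 4), (-3.0, 1.0, 7)]:
            assert fa.inclusive_value([c] * m, lam) == pytest.approx(
                c / lam + np.log(m), abs=1e-12
            )

    def test_overflow_safe(self):
        v = np.array([700.0, 650.0, 10.0])
        got = fa.inclusive_value(v, 0.5)
        # shifted reference computation
        a = v / 0.5
        ref = a.max() + np.log(np.exp(a - a.max()).sum())
        assert np.isfinite(got) and got == pytest.approx(ref, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            fa.inclusive_value([], 0.5)
        with pytest.raises(ValueError):
            fa.inclusive_value([0.0], 1.5)


class TestHarvestUtility:
    def _ctx(self, **kw):
        base = dict(
            forest_type="DF",
            stand_age=40.0,
            volume=200.0,
            elevation=100.0,
            climate=np.array([800.0, 14.0, 24.0, 0.0]),
            viable_types=("DF", "HW"),
            rents={"DF": 100.0, "HW": 60.0},
            prices={t: 50.0 for t in fa.FOREST_TYPES},
            yield_curve=fa.YieldCurve("DF", 400.0, 0.05, 2.0),
        )
        base.update(kw)
        return fa.ChoiceContext(**base)

    def test_all_zero_params(self):
        V = fa.harvest_utility(self._ctx(), fa.ChoiceParameters())
        assert all(v == 0.0 for v in V.values())

    def test_arithmetic(self):
        p = fa.ChoiceParameters()
        p.alpha_clear0, p.alpha_rev = -1.0, 0.002
        ctx = self._ctx(volume=20.0)  # price 50 * vol 20 = 1000
        assert fa.harvest_utility(ctx, p)["clearcut"] == pytest.approx(1.0, abs=1e-12)

    def test_carbon_tax_lowers_clearcut_only(self):
        p = fa.ChoiceParameters()
        p.alpha_rev = 0.001
        v0 = fa.harvest_utility(self._ctx(), p)
        v1 = fa.harvest_utility(self._ctx(carbon_tax_clear=500.0), p)
        assert v1["clearcut"] < v0["clearcut"]
        assert v1["partialcut"] == v0["partialcut"]
        assert v1["nocut"] == v0["nocut"]

    def test_missing_yield_curve(self):
        p = fa.ChoiceParameters()
        with pytest.raises(ValueError):
            fa.harvest_utility(self._ctx(yield_curve=None), p)


class TestReplantUtility:
    def test_zero_params(self):
        rng = np.random.default_rng(0)
        ctx = random_context(rng)
        V = fa.replant_utility(ctx, fa.ChoiceParameters())
        assert all(v == 0.0 for v in V.values())

    def test_rent_raises_only_that_type(self):
        rng = np.random.default_rng(1)
        ctx = random_context(rng)
        p = fa.ChoiceParameters()
        p.beta_rent = 0.01
        t0 = ctx.viable_types[0]
        V0 = fa.replant_utility(ctx, p)
        ctx.rents[t0] += 50.0
        V1 = fa.replant_utility(ctx, p)
        assert V1[t0] > V0[t0]
        for t in ctx.viable_types[1:]:
            assert V1[t] == V0[t]

    def test_warming_lowers_df_relative_to_hw(self):
        p = fa.generate_true_parameters(2)
        rng = np.random.default_rng(2)
        ctx = random_context(rng)
        ctx.viable_types = ("DF", "HW")
        ctx.rents = {"DF": 100.0, "HW": 100.0}
        V0 = fa.replant_utility(ctx, p)
        d = np.zeros(4)
        d[fa.CLIMATE_VARS.index("gs_tmean")] = 3.0
        ctx.climate = ctx.climate + d
        V1 = fa.replant_utility(ctx, p)
        gap0 = V0["DF"] - V0["HW"]
        gap1 = V1["DF"] - V1["HW"]
        # linear form: gap change equals -3 * (HW tmean slope - DF tmean slope)
        slope = p.beta_climate["HW"][1] - p.beta_climate["DF"][1]
        assert gap1 - gap0 == pytest.approx(-3.0 * slope, rel=1e-9)
        assert gap1 < gap0


class TestDisturbance:
    def test_uniform_when_zero(self):
        rng = np.random.default_rng(3)
        probs = fa.disturbance_probabilities(random_context(rng), fa.ChoiceParameters())
        assert all(v == pytest.approx(0.25, abs=1e-12) for v in probs.values())

    def test_hot_august_raises_fire(self):
        p = fa.generate_true_parameters(4)
        rng = np.random.default_rng(4)
        ctx = random_context(rng)
        p0 = fa.disturbance_probabilities(ctx, p)["fire"]
        ctx.climate = ctx.climate + np.array([0.0, 0.0, 5.0, 0.0])
        p1 = fa.disturbance_probabilities(ctx, p)["fire"]
        assert p1 > p0

    def test_matches_brute_force_softmax(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            ctx = random_context(rng)
            p = fa.generate_true_parameters(rng.integers(1 << 30))
            got = fa.disturbance_probabilities(ctx, p)
            x = np.concatenate([[1.0, ctx.volume], ctx.climate, [ctx.elevation]])
            u = np.array([p.gamma[d] @ x for d in fa.DISTURBANCE_OUTCOMES])
            ref = np.exp(u - u.max())
            ref /= ref.sum()
            for d, r in zip(fa.DISTURBANCE_OUTCOMES, ref):
                assert got[d] == pytest.approx(r, abs=1e-12)


class TestChoiceProbabilities:
    def test_hand_case_2_2_4(self):
        Vh = {k: 0.0 for k in fa.HARVEST_OPTIONS}
        sub = {
            "clearcut": {"DF": 0.0, "HW": 0.0},
            "partialcut": {"DF": 0.0, "HW": 0.0},
            "nocut": {d: 0.0 for d in fa.DISTURBANCE_OUTCOMES},
        }
        pr = fa.nested_probabilities(Vh, sub, {k: 1.0 for k in fa.HARVEST_OPTIONS})
        assert pr.p_harvest["nocut"] == pytest.approx(0.5, abs=1e-12)
        assert pr.p_harvest["clearcut"] == pytest.approx(0.25, abs=1e-12)
        for v in pr.p_joint.values():
            assert v == pytest.approx(0.125, abs=1e-12)

    def test_layers_normalize(self, true_params):
        rng = np.random.default_rng(6)
        for _ in range(50):
            pr = fa.choice_probabilities(random_context(rng), true_params)
            assert sum(pr.p_harvest.values()) == pytest.approx(1.0, abs=1e-12)
            for k in fa.HARVEST_OPTIONS:
                assert sum(pr.p_conditional[k].values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(pr.p_joint.values()) == pytest.approx(1.0, abs=1e-12)
            for (k, j), v in pr.p_joint.items():
                assert v == pytest.approx(
                    pr.p_harvest[k] * pr.p_conditional[k][j], abs=1e-14
                )

    def test_lambda_one_collapse(self, true_params):
        p = true_params.copy()
        p.lam = {k: 1.0 for k in fa.HARVEST_OPTIONS}
        rng = np.random.default_rng(7)
        for _ in range(100):
            ctx = random_context(rng)
            pr = fa.choice_probabilities(ctx, p)
            Vh = fa.harvest_utility(ctx, p)
            sub = {
                "clearcut": fa.replant_utility(ctx, p),
                "partialcut": {"keep": 0.0},
                "nocut": dict(
                    zip(
                        fa.DISTURBANCE_OUTCOMES,
                        fa.choice.__dict__["_disturbance_utilities"](ctx, p),
                    )
                ),
            }
            ref = flat_composite_probs(Vh, sub)
            for key, v in pr.p_joint.items():
                assert v == pytest.approx(ref[key], abs=1e-10)

    def test_translation_invariance_of_conditionals(self, true_params):
        rng = np.random.default_rng(8)
        ctx = random_context(rng)
        Vh = fa.harvest_utility(ctx, true_params)
        sub_u = {
            "clearcut": fa.replant_utility(ctx, true_params),
            "partialcut": {"keep": 0.0},
            "nocut": {d: 0.1 * i for i, d in enumerate(fa.DISTURBANCE_OUTCOMES)},
        }
        pr0 = fa.nested_probabilities(Vh, sub_u, true_params.lam)
        shifted = {k: dict(v) for k, v in sub_u.items()}
        c = 2.5
        shifted["clearcut"] = {j: v + c for j, v in shifted["clearcut"].items()}
        pr1 = fa.nested_probabilities(Vh, shifted, true_params.lam)
        for j in sub_u["clearcut"]:
            assert pr1.p_conditional["clearcut"][j] == pytest.approx(
                pr0.p_conditional["clearcut"][j], abs=1e-12
            )
        # the nest itself becomes more attractive: by exactly exp(c) in odds
        odds0 = pr0.p_harvest["clearcut"] / pr0.p_harvest["nocut"]
        odds1 = pr1.p_harvest["clearcut"] / pr1.p_harvest["nocut"]
        assert odds1 / odds0 == pytest.approx(np.exp(c), rel=1e-9)

    def test_overflow_safety(self):
        Vh = {"clearcut": 1000.0, "partialcut": -1000.0, "nocut": 0.0}
        sub = {
            "clearcut": {"DF": 900.0, "HW": -900.0},
            "partialcut": {"keep": 0.0},
            "nocut": {d: 500.0 for d in fa.DISTURBANCE_OUTCOMES},
        }
        pr = fa.nested_probabilities(Vh, sub, {k: 0.5 for k in fa.HARVEST_OPTIONS})
        vals = list(pr.p_joint.values())
        assert np.all(np.isfinite(vals))
        assert sum(vals) == pytest.approx(1.0, abs=1e-9)


class TestSampleChoice:
    def test_degenerate(self):
        pr = fa.ChoiceProbabilities(
            {"clearcut": 1.0, "partialcut": 0.0, "nocut": 0.0},
            {
                "clearcut": {"HW": 1.0, "DF": 0.0},
                "partialcut": {"keep": 1.0},
                "nocut": {d: 0.25 for d in fa.DISTURBANCE_OUTCOMES},
            },
        )
        rng = np.random.default_rng(0)
        assert all(
            fa.sample_choice(pr, rng) == ("clearcut", "HW") for _ in range(20)
        )

    def test_reproducible_stream(self, true_params):
        rng = np.random.default_rng(9)
        ctx = random_context(rng)
        pr = fa.choice_probabilities(ctx, true_params)
        a = fa.sample_choice(pr, np.random.default_rng(1234), size=50)
        b = fa.sample_choice(pr, np.random.default_rng(1234), size=50)
        assert a == b

    def test_frequencies_match_joint(self, true_params):
        rng = np.random.default_rng(10)
        ctx = random_context(rng)
        pr = fa.choice_probabilities(ctx, true_params)
        n = 100_000
        draws = fa.sample_choice(pr, np.random.default_rng(99), size=n)
        items = pr.joint_items()
        counts = {key: 0 for key, _ in items}
        for d in draws:
            counts[d] += 1
        obs = np.array([counts[key] for key, _ in items])
        exp = np.array([v for _, v in items]) * n
        keep = exp > 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.001
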