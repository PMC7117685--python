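"""The nested-logit land-value model.

A landowner's management choice is modeled in two levels.  The upper level
picks a harvest option k ∈ {clearcut, partialcut, nocut}; the lower level
picks a sub-nest outcome j — the replanted forest type after a cut, or the
natural fate {grow, fire, insects, disease} of an uncut stand.  With
sub-nest utilities V_{j|k}, inclusive value I_k = log Σ_j exp(V_{j|k}/λ_k)
and harvest utilities V_k, the joint choice probability is

    P(k, j) = exp(V_k + λ_k I_k) / Σ_k' exp(V_k' + λ_k' I_k')
            · exp(V_{j|k}/λ_k) / Σ_j' exp(V_{j'|k}/λ_k),

which collapses to a flat multinomial logit over (k, j) composites when all
λ_k = 1.  All computations are max-shifted so utilities of magnitude 10³
remain finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import (
    DISTURBANCE_OUTCOMES,
    HARVEST_OPTIONS,
    ChoiceConfig,
    ChoiceParameters,
)
from .economics import YieldCurve

__all__ = [
    "ChoiceContext",
    "ChoiceProbabilities",
    "harvest_utility",
    "replant_utility",
    "disturbance_probabilities",
    "inclusive_value",
    "nested_probabilities",
    "choice_probabilities",
    "sample_choice",
]


# ---------------------------------------------------------------------------
# Vectorized primitives (shared by estimation and the landscape simulator)


def softmax_masked(V: np.ndarray, axis: int = -1) -> np.ndarray:
    """Max-shifted softmax; -inf entries get probability exactly 0."""
    shift = np.max(V, axis=axis, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    with np.errstate(invalid="ignore"):
        e = np.exp(V - shift)
    e = np.where(np.isfinite(V), e, 0.0)
    return e / e.sum(axis=axis, keepdims=True)


def inclusive_value(sub_utilities, lambda_k: float) -> float:
    """Log-sum inclusive value I_k = log Σ_j exp(V_j / λ_k), max-shifted."""
    v = np.asarray(sub_utilities, float)
    if v.size == 0:
        raise ValueError("sub-utility vector must be nonempty")
    if not 0.0 < lambda_k <= 1.0:
        raise ValueError("lambda must lie in (0, 1]")
    return float(logsumexp(v / lambda_k))


def build_utilities(
    cov: dict[str, np.ndarray], params: ChoiceParameters, config: ChoiceConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble utility arrays for n records from covariate arrays.

    ``cov`` keys: clim (n,4), elev (n,), volume (n,), rents (n,6; non-viable
    entries ignored), viable (n,6) bool, rev_clear (n,), rev_partial (n,),
    rev_growth (n,).

    Returns (Vh (n,3), Vclear (n,6), Vpartial (n,6) or (n,1), Vnocut (n,4))
    with non-viable replant utilities set to -inf.
    """
    clim = cov["clim"]
    n = clim.shape[0]
    elev = cov["elev"]
    viable = cov["viable"]

    Vh = np.empty((n, 3))
    Vh[:, 0] = params.alpha_clear0 + params.alpha_rev * cov["rev_clear"]
    Vh[:, 1] = params.alpha_partial0 + params.alpha_rev * cov["rev_partial"]
    Vh[:, 2] = params.alpha_grow * cov["rev_growth"]

    Vc = (
        params.beta_intercept_vec()[None, :]
        + params.beta_rent * cov["rents"]
        + clim @ params.beta_climate_mat().T
        + elev[:, None] * params.beta_elev_vec()[None, :]
    )
    Vc = np.where(viable, Vc, -np.inf)

    if config.partial_replant:
        Vp = Vc
    else:
        Vp = np.zeros((n, 1))  # degenerate {keep} outcome

    G = params.gamma_mat()  # (4, 7): intercept, volume, 4 climate, elevation
    X = np.column_stack([np.ones(n), cov["volume"], clim, elev])
    Vn = X @ G.T
    return Vh, Vc, Vp, Vn


def nested_forward(
    Vh: np.ndarray,
    subs: tuple[np.ndarray, np.ndarray, np.ndarray],
    lam: np.ndarray,
) -> dict[str, np.ndarray]:
    """Evaluate all layers of the nested logit for n records at once.

    Returns P (n,3) nest probabilities, Q0/Q1/Q2 conditional probabilities,
    I (n,3) inclusive values, S (n,3) = Σ_j Q_{j|k} V_{j|k} (used by the
    analytic score), and W (n,3) = V_k + λ_k I_k.
    """
    n = Vh.shape[0]
    I = np.empty((n, 3))
    S = np.empty((n, 3))
    Qs = []
    for k in range(3):
        V = subs[k]
        A = V / lam[k]
        I[:, k] = logsumexp(A, axis=1)
        Q = softmax_masked(A, axis=1)
        Qs.append(Q)
        with np.errstate(invalid="ignore"):
            QV = np.where(Q > 0.0, Q * np.where(np.isfinite(V), V, 0.0), 0.0)
        S[:, k] = QV.sum(axis=1)
    W = Vh + lam[None, :] * I
    P = softmax_masked(W, axis=1)
    return {"P": P, "Q": Qs, "I": I, "S": S, "W": W}


def joint_matrix(P: np.ndarray, Qs: list[np.ndarray]) -> np.ndarray:
    """Concatenate P(k)·Q(j|k) into one (n, Σ m_k) joint probability matrix."""
    return np.concatenate(
        [P[:, [k]] * Qs[k] for k in range(3)], axis=1
    )


# ---------------------------------------------------------------------------
# Single-context API


@dataclass
class ChoiceContext:
    """Everything a landowner sees when choosing management for one plot-decade.

    ``rents`` are effective (carbon-augmented where applicable) annual rents
    per viable replant type; ``carbon_accrual`` is the carbon value ($/ha)
    the standing stand would sequester over the coming decade, added to the
    growth revenue of the no-cut option when the policy pays standing stands.
    """

    forest_type: str
    stand_age: float
    volume: float
    elevation: float
    climate: np.ndarray  # (4,) ordered as CLIMATE_VARS
    viable_types: tuple[str, ...]
    rents: dict[str, float]
    prices: dict[str, float]
    carbon_tax_clear: float = 0.0
    carbon_tax_partial: float = 0.0
    yield_curve: YieldCurve | None = None
    carbon_accrual: float = 0.0

    def __post_init__(self):
        self.climate = np.asarray(self.climate, float)
        if len(self.viable_types) == 0:
            raise ValueError("viable set must be nonempty")
        missing = [t for t in self.viable_types if t not in self.rents]
        if missing:
            raise ValueError(f"rents missing for viable types {missing}")
        if not np.all(np.isfinite(self.climate)):
            raise ValueError("climate fields must be finite")


@dataclass
class ChoiceProbabilities:
    """The three probability layers of one nested-logit evaluation."""

    p_harvest: dict[str, float]
    p_conditional: dict[str, dict[str, float]]

    @property
    def p_joint(self) -> dict[tuple[str, str], float]:
        return {
            (k, j): self.p_harvest[k] * q
            for k in self.p_harvest
            for j, q in self.p_conditional[k].items()
        }

    def joint_items(self) -> list[tuple[tuple[str, str], float]]:
        return list(self.p_joint.items())


def harvest_utility(
    ctx: ChoiceContext, params: ChoiceParameters, config: ChoiceConfig = ChoiceConfig()
) -> dict[str, float]:
    """Harvest-level utilities V_k from net revenues and revenue growth."""
    p = ctx.prices[ctx.forest_type]
    rev_clear = p * ctx.volume - ctx.carbon_tax_clear
    rev_partial = config.phi * p * ctx.volume - ctx.carbon_tax_partial
    if ctx.yield_curve is None:
        raise ValueError(f"missing yield curve for forest type {ctx.forest_type}")
    growth = p * (
        float(ctx.yield_curve(ctx.stand_age + 10.0))
        - float(ctx.yield_curve(ctx.stand_age))
    )
    growth += ctx.carbon_accrual
    return {
        "clearcut": params.alpha_clear0 + params.alpha_rev * rev_clear,
        "partialcut": params.alpha_partial0 + params.alpha_rev * rev_partial,
        "nocut": params.alpha_grow * growth,
    }


def replant_utility(
    ctx: ChoiceContext, params: ChoiceParameters
) -> dict[str, float]:
    """Replant-level utilities over the plot's viable forest types."""
    out = {}
    for t in ctx.viable_types:
        out[t] = float(
            params.beta_intercept[t]
            + params.beta_rent * ctx.rents[t]
            + ctx.climate @ np.asarray(params.beta_climate[t], float)
            + params.beta_elev[t] * ctx.elevation
        )
    return out


def _disturbance_utilities(ctx: ChoiceContext, params: ChoiceParameters) -> np.ndarray:
    x = np.concatenate([[1.0, ctx.volume], ctx.climate, [ctx.elevation]])
    return params.gamma_mat() @ x


def disturbance_probabilities(
    ctx: ChoiceContext, params: ChoiceParameters
) -> dict[str, float]:
    """Multinomial-logit distribution over {grow, fire, insects, disease}."""
    p = softmax_masked(_disturbance_utilities(ctx, params))
    return dict(zip(DISTURBANCE_OUTCOMES, p.tolist()))


def nested_probabilities(
    harvest_utilities: dict[str, float],
    sub_utilities: dict[str, dict[str, float]],
    lambdas: dict[str, float],
) -> ChoiceProbabilities:
    """Assemble all three probability layers from utilities and λ."""
    Vh = np.array([[harvest_utilities[k] for k in HARVEST_OPTIONS]])
    subs = []
    labels = []
    for k in HARVEST_OPTIONS:
        items = list(sub_utilities[k].items())
        if not items:
            raise ValueError(f"empty sub-nest for {k}")
        labels.append([j for j, _ in items])
        subs.append(np.array([[v for _, v in items]]))
    lam = np.array([lambdas[k] for k in HARVEST_OPTIONS])
    if np.any(lam <= 0.0) or np.any(lam > 1.0):
        raise ValueError("all lambda must lie in (0, 1]")
    fw = nested_forward(Vh, tuple(subs), lam)
    p_harvest = dict(zip(HARVEST_OPTIONS, fw["P"][0].tolist()))
    p_cond = {
        k: dict(zip(labels[i], fw["Q"][i][0].tolist()))
        for i, k in enumerate(HARVEST_OPTIONS)
    }
    return ChoiceProbabilities(p_harvest, p_cond)


def choice_probabilities(
    ctx: ChoiceContext, params: ChoiceParameters, config: ChoiceConfig = ChoiceConfig()
) -> ChoiceProbabilities:
    """Eq-style nested-logit probabilities for one choice context."""
    Vh = harvest_utility(ctx, params, config)
    replant = replant_utility(ctx, params)
    dist = dict(
        zip(DISTURBANCE_OUTCOMES, _disturbance_utilities(ctx, params).tolist())
    )
    partial_sub = replant if config.partial_replant else {"keep": 0.0}
    sub = {"clearcut": replant, "partialcut": partial_sub, "nocut": dist}
    return nested_probabilities(Vh, sub, params.lam)


def sample_choice(
    probs: ChoiceProbabilities, rng: np.random.Generator, size: int | None = None
):
    """Draw (k, j) from the joint distribution; reproducible given the stream.

    With ``size`` given, returns a list of (k, j) tuples.
    """
    items = probs.joint_items()
    p = np.array([v for _, v in items])
    cum = np.cumsum(p)
    cum[-1] = 1.0
    u = rng.uniform(size=size)
    idx = np.searchsorted(cum, u, side="right")
    if size is None:
        return items[int(idx)][0]
    return [items[int(i)][0] for i in np.atleast_1d(idx)]
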