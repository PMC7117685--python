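"""Maximum-likelihood estimation of the nested-logit choice parameters.

`NestedLogitModel` is built from a `ChoiceDataset` (observed or simulated
plot-decade management choices) and `fit()` returns a `NestedLogitResults`
carrying the estimates, their standard errors (inverse numerical Hessian),
convergence diagnostics and a `summary()` table — the usual Model/Results
split.  Module-level wrappers (`nested_logit_loglik`, `fit_nested_logit`,
`simulate_choice_dataset`, `marginal_effect`) expose the same machinery
functionally.

Numerics: covariates are standardized internally (an exact linear
re-parameterisation of the likelihood, mapped back to the natural scale with
a delta-method Jacobian), the score is analytic, and each inclusive-value
coefficient λ is estimated through a logistic transform onto (0.05, 1.0) to
avoid boundary pathologies.  λ of a degenerate sub-nest (the partial-cut
{keep} outcome under the default nest structure) is structurally
unidentified and fixed at 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .choice import (
    build_utilities,
    choice_probabilities,
    joint_matrix,
    nested_forward,
    softmax_masked,
)
from .core import (
    CLIMATE_VARS,
    DISTURBANCE_OUTCOMES,
    FOREST_TYPES,
    HARVEST_OPTIONS,
    ChoiceConfig,
    ChoiceParameters,
    REFERENCE_FOREST_TYPE,
    viable_types_from_str,
)
from .economics import DEFAULT_PRICES, build_rent_table, default_yield_curves

__all__ = [
    "ChoiceDataset",
    "NestedLogitModel",
    "NestedLogitResults",
    "simulate_choice_dataset",
    "nested_logit_loglik",
    "fit_nested_logit",
    "marginal_effect",
]

_NONREF_TYPES = tuple(t for t in FOREST_TYPES if t != REFERENCE_FOREST_TYPE)
_EST_DISTURBANCES = tuple(d for d in DISTURBANCE_OUTCOMES if d != "grow")
_RENT_COLS = [f"rent_{t}" for t in FOREST_TYPES]
_VIABLE_COLS = [f"viable_{t}" for t in FOREST_TYPES]


# ---------------------------------------------------------------------------
# Dataset


@dataclass
class ChoiceDataset:
    """Observed (or simulated) choice records with full per-record context.

    One row per decision: case covariates (four climate normals, elevation,
    stand volume), the three harvest-level revenue measures, effective rents
    for the six forest types (NaN where a type is not viable), the viability
    mask, and the observed choice (chosen_k, chosen_j).
    """

    df: pd.DataFrame
    config: ChoiceConfig = field(default_factory=ChoiceConfig)

    def __post_init__(self):
        required = (
            list(CLIMATE_VARS)
            + ["elevation", "volume", "rev_clear", "rev_partial", "rev_growth"]
            + _RENT_COLS
            + _VIABLE_COLS
            + ["chosen_k", "chosen_j"]
        )
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        viable = self.df[_VIABLE_COLS].to_numpy(bool)
        if (viable.sum(axis=1) < 2).any():
            raise ValueError("every record needs at least 2 viable alternatives")
        replants = self.df.chosen_k == "clearcut"
        if self.config.partial_replant:
            replants = replants | (self.df.chosen_k == "partialcut")
        for i in np.flatnonzero(replants.to_numpy()):
            j = self.df.chosen_j.iloc[i]
            if j not in FOREST_TYPES or not viable[i, FOREST_TYPES.index(j)]:
                raise ValueError("observed replant choice outside the viable set")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["cfg_phi"] = self.config.phi
        out["cfg_partial_replant"] = int(self.config.partial_replant)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChoiceDataset":
        df = pd.read_csv(path)
        cfg = ChoiceConfig(
            phi=float(df.pop("cfg_phi").iloc[0]),
            partial_replant=bool(df.pop("cfg_partial_replant").iloc[0]),
        )
        return cls(df, cfg)

    # -- arrays for the vectorized likelihood -------------------------------

    def covariates(self) -> dict[str, np.ndarray]:
        df = self.df
        rents = df[_RENT_COLS].to_numpy(float)
        return {
            "clim": df[list(CLIMATE_VARS)].to_numpy(float),
            "elev": df["elevation"].to_numpy(float),
            "volume": df["volume"].to_numpy(float),
            "rents": np.nan_to_num(rents, nan=0.0),
            "viable": df[_VIABLE_COLS].to_numpy(bool),
            "rev_clear": df["rev_clear"].to_numpy(float),
            "rev_partial": df["rev_partial"].to_numpy(float),
            "rev_growth": df["rev_growth"].to_numpy(float),
        }

    def chosen_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(k index in HARVEST_OPTIONS, j index within that nest) per record."""
        k_idx = np.array([HARVEST_OPTIONS.index(k) for k in self.df.chosen_k])
        j_idx = np.empty(len(self.df), int)
        for i, (k, j) in enumerate(zip(self.df.chosen_k, self.df.chosen_j)):
            if k == "nocut":
                j_idx[i] = DISTURBANCE_OUTCOMES.index(j)
            elif k == "partialcut" and not self.config.partial_replant:
                j_idx[i] = 0  # degenerate {keep}
            else:
                j_idx[i] = FOREST_TYPES.index(j)
        return k_idx, j_idx


def _joint_labels(config: ChoiceConfig) -> list[tuple[str, str]]:
    labels = [("clearcut", t) for t in FOREST_TYPES]
    if config.partial_replant:
        labels += [("partialcut", t) for t in FOREST_TYPES]
    else:
        labels += [("partialcut", "keep")]
    labels += [("nocut", d) for d in DISTURBANCE_OUTCOMES]
    return labels


def simulate_choice_dataset(
    plots: pd.DataFrame,
    true_params: ChoiceParameters,
    n_periods: int = 1,
    seed: int = 0,
    config: ChoiceConfig = ChoiceConfig(),
) -> ChoiceDataset:
    """Simulate a choice dataset from known parameters.

    Each period re-draws stand state (age, hence volume and revenues) and
    perturbs regional rents and prices, so the records span the covariate
    space needed to identify all coefficients; choices are then sampled from
    the model's joint probabilities under ``true_params``.
    """
    if len(plots) == 0:
        raise ValueError("plots table must be nonempty")
    rng = np.random.default_rng(seed)
    curves = default_yield_curves()
    rent_table = build_rent_table(
        sorted(plots.ecoregion_id.unique()), curves, DEFAULT_PRICES
    )
    base_rent = {
        (int(r.ecoregion_id), r.forest_type): r.rent
        for r in rent_table.table.itertuples()
    }
    type_idx = plots["forest_type"].map(FOREST_TYPES.index).to_numpy()
    viable = np.zeros((len(plots), len(FOREST_TYPES)), bool)
    for i, s in enumerate(plots["viable_types"]):
        for t in viable_types_from_str(s):
            viable[i, FOREST_TYPES.index(t)] = True

    frames = []
    for _ in range(n_periods):
        n = len(plots)
        age = rng.uniform(5.0, 90.0, n).round()
        price_mult = rng.uniform(0.75, 1.25)
        rent_mult = rng.uniform(0.8, 1.2)
        vol = np.empty(n)
        growth = np.empty(n)
        price_own = np.empty(n)
        for j, t in enumerate(FOREST_TYPES):
            m = type_idx == j
            vol[m] = curves[t](age[m]) * np.exp(rng.normal(0.0, 0.25, int(m.sum())))
            growth[m] = curves[t](age[m] + 10.0) - curves[t](age[m])
            price_own[m] = DEFAULT_PRICES[t] * price_mult
        rents = np.full((n, len(FOREST_TYPES)), np.nan)
        for i, eco in enumerate(plots.ecoregion_id.to_numpy()):
            for j, t in enumerate(FOREST_TYPES):
                if viable[i, j]:
                    rents[i, j] = base_rent[(int(eco), t)] * rent_mult + rng.normal(0, 8)
        rec = pd.DataFrame(
            {
                **{v: plots[v].to_numpy() for v in CLIMATE_VARS},
                "elevation": plots["elevation"].to_numpy(),
                "volume": vol,
                "rev_clear": price_own * vol,
                "rev_partial": config.phi * price_own * vol,
                "rev_growth": price_own * growth,
            }
        )
        for j, t in enumerate(FOREST_TYPES):
            rec[f"rent_{t}"] = rents[:, j]
            rec[f"viable_{t}"] = viable[:, j].astype(int)
        frames.append(rec)
    df = pd.concat(frames, ignore_index=True)

    cov = {
        "clim": df[list(CLIMATE_VARS)].to_numpy(float),
        "elev": df["elevation"].to_numpy(float),
        "volume": df["volume"].to_numpy(float),
        "rents": np.nan_to_num(df[_RENT_COLS].to_numpy(float), nan=0.0),
        "viable": df[_VIABLE_COLS].to_numpy(bool),
        "rev_clear": df["rev_clear"].to_numpy(float),
        "rev_partial": df["rev_partial"].to_numpy(float),
        "rev_growth": df["rev_growth"].to_numpy(float),
    }
    Vh, Vc, Vp, Vn = build_utilities(cov, true_params, config)
    fw = nested_forward(Vh, (Vc, Vp, Vn), true_params.lam_vec())
    J = joint_matrix(fw["P"], fw["Q"])
    cum = np.cumsum(J, axis=1)
    cum[:, -1] = 1.0
    u = rng.uniform(size=len(df))
    idx = (u[:, None] > cum).sum(axis=1)
    labels = _joint_labels(config)
    df["chosen_k"] = [labels[i][0] for i in idx]
    df["chosen_j"] = [labels[i][1] for i in idx]
    return ChoiceDataset(df, config)


# ---------------------------------------------------------------------------
# Internal parameterisation: packing, scaling, λ transform

_LAM_LO, _LAM_SPAN = 0.05, 0.95


def _lam_from_t(t):
    return _LAM_LO + _LAM_SPAN / (1.0 + np.exp(-t))


def _t_from_lam(lam):
    q = (lam - _LAM_LO) / _LAM_SPAN
    q = np.clip(q, 1e-9, 1.0 - 1e-9)
    return np.log(q / (1.0 - q))


class _Parameterisation:
    """Mapping between the packed (scaled) vector and ChoiceParameters."""

    def __init__(self, cov: dict[str, np.ndarray], config: ChoiceConfig):
        self.config = config
        clim = cov["clim"]
        self.m_clim = clim.mean(axis=0)
        self.s_clim = np.maximum(clim.std(axis=0), 1e-9)
        self.m_elev = cov["elev"].mean()
        self.s_elev = max(cov["elev"].std(), 1e-9)
        self.m_vol = cov["volume"].mean()
        self.s_vol = max(cov["volume"].std(), 1e-9)
        rev = np.concatenate([cov["rev_clear"], cov["rev_partial"]])
        self.m_rev = rev.mean()
        self.s_rev = max(rev.std(), 1e-9)
        self.s_growth = max(cov["rev_growth"].std(), 1e-9)
        vr = cov["rents"][cov["viable"]]
        self.m_rent = vr.mean()
        self.s_rent = max(vr.std(), 1e-9)
        self.est_lam_nests = ["clearcut", "nocut"]
        if config.partial_replant:
            self.est_lam_nests.insert(1, "partialcut")
        self.names = self._build_names()
        self.n_params = len(self.names)

    def _build_names(self) -> list[str]:
        names = ["alpha_clear0", "alpha_partial0", "alpha_rev", "alpha_grow", "beta_rent"]
        for t in _NONREF_TYPES:
            names.append(f"beta0[{t}]")
            names += [f"beta[{t}]:{v}" for v in CLIMATE_VARS]
            names.append(f"beta[{t}]:elev")
        for d in _EST_DISTURBANCES:
            names.append(f"gamma0[{d}]")
            names.append(f"gamma[{d}]:volume")
            names += [f"gamma[{d}]:{v}" for v in CLIMATE_VARS]
            names.append(f"gamma[{d}]:elev")
        names += [f"lambda[{k}]" for k in self.est_lam_nests]
        return names

    def scale_covariates(self, cov: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = dict(cov)
        out["clim"] = (cov["clim"] - self.m_clim) / self.s_clim
        out["elev"] = (cov["elev"] - self.m_elev) / self.s_elev
        out["volume"] = (cov["volume"] - self.m_vol) / self.s_vol
        rents = np.where(cov["viable"], (cov["rents"] - self.m_rent) / self.s_rent, 0.0)
        out["rents"] = rents
        out["rev_clear"] = (cov["rev_clear"] - self.m_rev) / self.s_rev
        out["rev_partial"] = (cov["rev_partial"] - self.m_rev) / self.s_rev
        out["rev_growth"] = cov["rev_growth"] / self.s_growth  # no centering: nocut has no intercept
        return out

    def unpack_scaled(self, x: np.ndarray) -> ChoiceParameters:
        """Packed vector -> ChoiceParameters on the *scaled-covariate* space."""
        p = ChoiceParameters()
        p.alpha_clear0, p.alpha_partial0, p.alpha_rev, p.alpha_grow, p.beta_rent = x[:5]
        i = 5
        for t in _NONREF_TYPES:
            p.beta_intercept[t] = x[i]
            p.beta_climate[t] = x[i + 1 : i + 5].copy()
            p.beta_elev[t] = x[i + 5]
            i += 6
        for d in _EST_DISTURBANCES:
            p.gamma[d] = x[i : i + 7].copy()
            i += 7
        lam = {k: 1.0 for k in HARVEST_OPTIONS}
        for k in self.est_lam_nests:
            lam[k] = float(_lam_from_t(x[i]))
            i += 1
        p.lam = lam
        return p

    def unscale(self, ps: ChoiceParameters) -> ChoiceParameters:
        """Scaled-space parameters -> natural-scale parameters (exact map)."""
        p = ps.copy()
        p.beta_rent = ps.beta_rent / self.s_rent
        shift_rent = p.beta_rent * self.m_rent
        for t in _NONREF_TYPES:
            bc = np.asarray(ps.beta_climate[t]) / self.s_clim
            be = ps.beta_elev[t] / self.s_elev
            p.beta_climate[t] = bc
            p.beta_elev[t] = be
            p.beta_intercept[t] = (
                ps.beta_intercept[t] - bc @ self.m_clim - be * self.m_elev
            )
        for d in _EST_DISTURBANCES:
            g = np.asarray(ps.gamma[d], float).copy()
            g[1] = g[1] / self.s_vol
            g[2:6] = g[2:6] / self.s_clim
            g[6] = g[6] / self.s_elev
            g[0] = (
                ps.gamma[d][0]
                - g[1] * self.m_vol
                - g[2:6] @ self.m_clim
                - g[6] * self.m_elev
            )
            p.gamma[d] = g
        p.alpha_rev = ps.alpha_rev / self.s_rev
        p.alpha_grow = ps.alpha_grow / self.s_growth
        p.alpha_clear0 = ps.alpha_clear0 - p.alpha_rev * self.m_rev - shift_rent
        p.alpha_partial0 = ps.alpha_partial0 - p.alpha_rev * self.m_rev
        if self.config.partial_replant:
            p.alpha_partial0 -= shift_rent
        return p

    def pack_natural(self, p: ChoiceParameters) -> np.ndarray:
        """Natural-scale ChoiceParameters -> packed scaled vector (inverse map)."""
        x = np.empty(self.n_params)
        b_rent_s = p.beta_rent * self.s_rent
        shift_rent = p.beta_rent * self.m_rent
        a_rev_s = p.alpha_rev * self.s_rev
        x[0] = p.alpha_clear0 + p.alpha_rev * self.m_rev + shift_rent
        x[1] = p.alpha_partial0 + p.alpha_rev * self.m_rev + (
            shift_rent if self.config.partial_replant else 0.0
        )
        x[2] = a_rev_s
        x[3] = p.alpha_grow * self.s_growth
        x[4] = b_rent_s
        i = 5
        for t in _NONREF_TYPES:
            bc = np.asarray(p.beta_climate[t], float)
            x[i] = p.beta_intercept[t] + bc @ self.m_clim + p.beta_elev[t] * self.m_elev
            x[i + 1 : i + 5] = bc * self.s_clim
            x[i + 5] = p.beta_elev[t] * self.s_elev
            i += 6
        for d in _EST_DISTURBANCES:
            g = np.asarray(p.gamma[d], float)
            x[i] = (
                g[0]
                + g[1] * self.m_vol
                + g[2:6] @ self.m_clim
                + g[6] * self.m_elev
            )
            x[i + 1] = g[1] * self.s_vol
            x[i + 2 : i + 6] = g[2:6] * self.s_clim
            x[i + 6] = g[6] * self.s_elev
            i += 7
        for k in self.est_lam_nests:
            x[i] = _t_from_lam(p.lam[k])
            i += 1
        return x

    def natural_vector(self, x: np.ndarray) -> np.ndarray:
        """Packed scaled vector -> flat vector of natural-scale parameters."""
        p = self.unscale(self.unpack_scaled(x))
        out = [p.alpha_clear0, p.alpha_partial0, p.alpha_rev, p.alpha_grow, p.beta_rent]
        for t in _NONREF_TYPES:
            out.append(p.beta_intercept[t])
            out.extend(np.asarray(p.beta_climate[t]))
            out.append(p.beta_elev[t])
        for d in _EST_DISTURBANCES:
            out.extend(np.asarray(p.gamma[d]))
        for k in self.est_lam_nests:
            out.append(p.lam[k])
        return np.array(out)


def params_to_vector(p: ChoiceParameters, config: ChoiceConfig) -> np.ndarray:
    """Flat natural-scale vector (same layout as the fitted coefficient table)."""
    out = [p.alpha_clear0, p.alpha_partial0, p.alpha_rev, p.alpha_grow, p.beta_rent]
    for t in _NONREF_TYPES:
        out.append(p.beta_intercept[t])
        out.extend(np.asarray(p.beta_climate[t]))
        out.append(p.beta_elev[t])
    for d in _EST_DISTURBANCES:
        out.extend(np.asarray(p.gamma[d]))
    nests = ["clearcut", "nocut"]
    if config.partial_replant:
        nests.insert(1, "partialcut")
    for k in nests:
        out.append(p.lam[k])
    return np.array(out)


# ---------------------------------------------------------------------------
# Likelihood and analytic score


def _loglik_core(
    x: np.ndarray,
    spec: _Parameterisation,
    cov_scaled: dict[str, np.ndarray],
    k_idx: np.ndarray,
    j_idx: np.ndarray,
    want_grad: bool,
):
    p = spec.unpack_scaled(x)
    lam = p.lam_vec()
    Vh, Vc, Vp, Vn = build_utilities(cov_scaled, p, spec.config)
    subs = (Vc, Vp, Vn)
    fw = nested_forward(Vh, subs, lam)
    P, Qs, I, S = fw["P"], fw["Q"], fw["I"], fw["S"]
    n = len(k_idx)
    rows = np.arange(n)
    ll = np.log(P[rows, k_idx]).sum()
    for k in range(3):
        m = k_idx == k
        ll += np.log(Qs[k][m, j_idx[m]]).sum()
    if not want_grad:
        return ll, None

    D = np.zeros((n, 3))  # d ll / d Vh_k  = onehot - P
    D[rows, k_idx] = 1.0
    dW = D - P

    grad = np.zeros(spec.n_params)
    # harvest-level coefficients
    grad[0] = dW[:, 0].sum()
    grad[1] = dW[:, 1].sum()
    grad[2] = dW[:, 0] @ cov_scaled["rev_clear"] + dW[:, 1] @ cov_scaled["rev_partial"]
    grad[3] = dW[:, 2] @ cov_scaled["rev_growth"]

    # d ll / d V_{j|k}
    dV = []
    for k in range(3):
        m_k = (k_idx == k).astype(float)
        E = np.zeros_like(Qs[k])
        sel = k_idx == k
        E[np.flatnonzero(sel), j_idx[sel]] = 1.0
        term = dW[:, [k]] * Qs[k] + m_k[:, None] * (E - Qs[k]) / lam[k]
        dV.append(term)

    dVc_tot = dV[0] + (dV[1] if spec.config.partial_replant else 0.0)
    clim = cov_scaled["clim"]
    elev = cov_scaled["elev"]
    grad[4] = float((dVc_tot * cov_scaled["rents"]).sum())
    i = 5
    for t in _NONREF_TYPES:
        jcol = FOREST_TYPES.index(t)
        col = dVc_tot[:, jcol]
        grad[i] = col.sum()
        grad[i + 1 : i + 5] = col @ clim
        grad[i + 5] = col @ elev
        i += 6
    X = np.column_stack([np.ones(n), cov_scaled["volume"], clim, elev])
    for d in _EST_DISTURBANCES:
        dcol = DISTURBANCE_OUTCOMES.index(d)
        grad[i : i + 7] = dV[2][:, dcol] @ X
        i += 7

    # λ gradients (natural λ, then chain through the logistic transform)
    for k_name in spec.est_lam_nests:
        k = HARVEST_OPTIONS.index(k_name)
        m = k_idx == k
        Vsub = subs[k]
        Vchosen = np.zeros(n)
        fin = np.where(np.isfinite(Vsub), Vsub, 0.0)
        Vchosen[m] = fin[np.flatnonzero(m), j_idx[m]]
        dlam = (dW[:, k] * (I[:, k] - S[:, k] / lam[k])).sum()
        dlam += ((S[:, k] - Vchosen)[m] / lam[k] ** 2).sum()
        sig = (lam[k] - _LAM_LO) / _LAM_SPAN
        grad[i] = dlam * _LAM_SPAN * sig * (1.0 - sig)
        i += 1
    return ll, grad


def nested_logit_loglik(params: ChoiceParameters, data: ChoiceDataset) -> float:
    """Log-likelihood of the data at the given (natural-scale) parameters."""
    params.validate()
    cov = data.covariates()
    Vh, Vc, Vp, Vn = build_utilities(cov, params, data.config)
    fw = nested_forward(Vh, (Vc, Vp, Vn), params.lam_vec())
    k_idx, j_idx = data.chosen_indices()
    rows = np.arange(len(data))
    ll = np.log(fw["P"][rows, k_idx]).sum()
    for k in range(3):
        m = k_idx == k
        ll += np.log(fw["Q"][k][m, j_idx[m]]).sum()
    return float(ll)


# ---------------------------------------------------------------------------
# Model / Results


class NestedLogitModel:
    """Nested-logit model of harvest and replant choices, built from a dataset."""

    def __init__(self, data: ChoiceDataset):
        self.data = data
        self.config = data.config
        self._cov = data.covariates()
        self.spec = _Parameterisation(self._cov, self.config)
        self._cov_scaled = self.spec.scale_covariates(self._cov)
        self._k_idx, self._j_idx = data.chosen_indices()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ChoiceConfig = ChoiceConfig()):
        return cls(ChoiceDataset(df, config))

    def loglike(self, params: ChoiceParameters) -> float:
        return nested_logit_loglik(params, self.data)

    def _negloglike_and_grad(self, x: np.ndarray):
        n = len(self._k_idx)
        ll, g = _loglik_core(
            x, self.spec, self._cov_scaled, self._k_idx, self._j_idx, True
        )
        return -ll / n, -g / n

    def fit(
        self,
        init: ChoiceParameters | None = None,
        tol: float = 1e-9,
        maxiter: int = 3000,
        method: str = "full",
        compute_se: bool = True,
    ) -> "NestedLogitResults":
        """Quasi-Newton maximization of the log-likelihood.

        ``method='sequential'`` first fits the sub-nest logits, then the
        harvest level with inclusive values, and uses that as the starting
        point for the full-information maximization (a fallback when the
        joint problem stalls from a cold start).
        """
        if init is not None:
            x0 = self.spec.pack_natural(init)
        elif method == "sequential":
            x0 = self._sequential_start()
        else:
            x0 = np.zeros(self.spec.n_params)
            x0[-len(self.spec.est_lam_nests):] = _t_from_lam(0.7)
        n_lam = len(self.spec.est_lam_nests)
        bounds = [(None, None)] * (self.spec.n_params - n_lam) + [(-7.5, 7.5)] * n_lam
        res = minimize(
            self._negloglike_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        n = len(self._k_idx)
        xhat = res.x
        params_scaled = self.spec.unpack_scaled(xhat)
        params = self.spec.unscale(params_scaled)
        bse = cov_nat = None
        if compute_se:
            H = self._hessian(xhat)
            cov_scaled = _robust_inv(H)
            Jac = _numeric_jacobian(self.spec.natural_vector, xhat)
            cov_nat = Jac @ cov_scaled @ Jac.T
            bse = np.sqrt(np.maximum(np.diag(cov_nat), 0.0))
        return NestedLogitResults(
            model=self,
            params=params,
            params_vector=self.spec.natural_vector(xhat),
            bse=bse,
            cov_params=cov_nat,
            llf=float(-res.fun * n),
            converged=bool(res.success),
            niter=int(res.nit),
            message=str(res.message),
        )

    def _hessian(self, x: np.ndarray) -> np.ndarray:
        """Central finite differences of the analytic score of -loglik/n."""
        p = len(x)
        H = np.empty((p, p))
        h = 1e-5 * (1.0 + np.abs(x))
        for i in range(p):
            xp = x.copy()
            xp[i] += h[i]
            xm = x.copy()
            xm[i] -= h[i]
            _, gp = self._negloglike_and_grad(xp)
            _, gm = self._negloglike_and_grad(xm)
            H[i] = (gp - gm) / (2.0 * h[i])
        H = 0.5 * (H + H.T)
        return H * len(self._k_idx)  # Hessian of -loglik (not mean)

    def _sequential_start(self) -> np.ndarray:
        """Two-step starting values: within-nest MNLs, then nest-level logit."""
        cov = self._cov_scaled
        n = len(self._k_idx)
        # Step 1a: replant MNL on clear-cut (and partial, if it replants) records
        sel = self._k_idx == 0
        if self.config.partial_replant:
            sel = sel | (self._k_idx == 1)
        b = _fit_mnl_replant(cov, sel, self._j_idx)
        # Step 1b: disturbance MNL on no-cut records
        g = _fit_mnl_disturbance(cov, self._k_idx == 2, self._j_idx)
        x0 = np.zeros(self.spec.n_params)
        x0[4] = b["rent"]
        i = 5
        for t in _NONREF_TYPES:
            blk = b[t]
            x0[i : i + 6] = blk
            i += 6
        for d in _EST_DISTURBANCES:
            x0[i : i + 7] = g[d]
            i += 7
        x0[i:] = _t_from_lam(0.8)
        return x0


def _robust_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def _numeric_jacobian(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    f0 = f(x)
    J = np.empty((len(f0), len(x)))
    for i in range(len(x)):
        step = h * (1.0 + abs(x[i]))
        xp = x.copy()
        xp[i] += step
        xm = x.copy()
        xm[i] -= step
        J[:, i] = (f(xp) - f(xm)) / (2.0 * step)
    return J


def _fit_mnl_replant(cov, sel, j_idx):
    """Plain MNL over forest types on the selected records (scaled covariates)."""
    clim = cov["clim"][sel]
    elev = cov["elev"][sel]
    rents = cov["rents"][sel]
    viable = cov["viable"][sel]
    chosen = j_idx[sel]
    n = sel.sum()
    nt = len(_NONREF_TYPES)
    p0 = np.zeros(1 + 6 * nt)

    def unpack(x):
        return x[0], x[1:].reshape(nt, 6)

    def nll(x):
        rent_b, blocks = unpack(x)
        V = rent_b * rents
        for a, t in enumerate(_NONREF_TYPES):
            jcol = FOREST_TYPES.index(t)
            V[:, jcol] += blocks[a, 0] + clim @ blocks[a, 1:5] + elev * blocks[a, 5]
        V = np.where(viable, V, -np.inf)
        Q = softmax_masked(V, axis=1)
        rows = np.arange(n)
        ll = np.log(np.maximum(Q[rows, chosen], 1e-300)).sum()
        E = np.zeros_like(Q)
        E[rows, chosen] = 1.0
        dV = E - Q
        g = np.empty_like(x)
        g[0] = (dV * rents).sum()
        for a, t in enumerate(_NONREF_TYPES):
            jcol = FOREST_TYPES.index(t)
            col = dV[:, jcol]
            g[1 + 6 * a] = col.sum()
            g[2 + 6 * a : 6 + 6 * a] = col @ clim
            g[6 + 6 * a] = col @ elev
        return -ll / n, -g / n

    res = minimize(nll, p0, jac=True, method="L-BFGS-B", options={"maxiter": 300})
    rent_b, blocks = unpack(res.x)
    out = {"rent": rent_b}
    for a, t in enumerate(_NONREF_TYPES):
        out[t] = blocks[a]
    return out


def _fit_mnl_disturbance(cov, sel, j_idx):
    clim = cov["clim"][sel]
    X = np.column_stack(
        [np.ones(sel.sum()), cov["volume"][sel], clim, cov["elev"][sel]]
    )
    chosen = j_idx[sel]
    n = sel.sum()
    nd = len(_EST_DISTURBANCES)

    def nll(x):
        G = x.reshape(nd, 7)
        V = np.zeros((n, 4))
        for a, d in enumerate(_EST_DISTURBANCES):
            V[:, DISTURBANCE_OUTCOMES.index(d)] = X @ G[a]
        Q = softmax_masked(V, axis=1)
        rows = np.arange(n)
        ll = np.log(np.maximum(Q[rows, chosen], 1e-300)).sum()
        E = np.zeros_like(Q)
        E[rows, chosen] = 1.0
        dV = E - Q
        g = np.empty((nd, 7))
        for a, d in enumerate(_EST_DISTURBANCES):
            g[a] = dV[:, DISTURBANCE_OUTCOMES.index(d)] @ X
        return -ll / n, -g.ravel() / n

    res = minimize(
        nll, np.zeros(nd * 7), jac=True, method="L-BFGS-B", options={"maxiter": 300}
    )
    G = res.x.reshape(nd, 7)
    return {d: G[a] for a, d in enumerate(_EST_DISTURBANCES)}


@dataclass
class NestedLogitResults:
    """Estimates, uncertainties and diagnostics of a fitted nested logit."""

    model: NestedLogitModel
    params: ChoiceParameters
    params_vector: np.ndarray
    bse: np.ndarray | None
    cov_params: np.ndarray | None
    llf: float
    converged: bool
    niter: int
    message: str = ""

    @property
    def names(self) -> list[str]:
        return self.model.spec.names

    @property
    def nobs(self) -> int:
        return len(self.model.data)

    def coef_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({"coef": self.params_vector}, index=self.names)
        if self.bse is not None:
            tab["std err"] = self.bse
            with np.errstate(divide="ignore", invalid="ignore"):
                tab["z"] = tab["coef"] / tab["std err"]
        return tab

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Nested logit of forest management choices\n")
        buf.write(f"  observations: {self.nobs}\n")
        buf.write(f"  log-likelihood: {self.llf:.3f}\n")
        buf.write(f"  converged: {self.converged} ({self.niter} iterations)\n\n")
        buf.write(self.coef_table().to_string(float_format=lambda v: f"{v: .6g}"))
        return buf.getvalue()


def fit_nested_logit(
    data: ChoiceDataset,
    init: ChoiceParameters | None = None,
    tol: float = 1e-9,
) -> tuple[ChoiceParameters, np.ndarray | None, bool]:
    """Functional wrapper: returns (estimate, standard errors, converged)."""
    res = NestedLogitModel(data).fit(init=init, tol=tol)
    return res.params, res.bse, res.converged


# ---------------------------------------------------------------------------
# Marginal effects


def marginal_effect(
    params: ChoiceParameters,
    ctx,
    covariate: str,
    delta: float,
    config: ChoiceConfig = ChoiceConfig(),
) -> dict[tuple[str, str], float]:
    """Finite-difference change in joint choice probabilities.

    ``ctx`` is a ChoiceContext or a sequence of them; the effect is the mean
    probability change per joint alternative over the supplied contexts.
    The effects sum to zero across the full joint choice set.
    """
    from dataclasses import replace as _dc_replace

    ctxs = ctx if isinstance(ctx, (list, tuple)) else [ctx]
    acc: dict[tuple[str, str], float] = {}
    for c in ctxs:
        if covariate in CLIMATE_VARS:
            clim = np.array(c.climate, float)
            clim[CLIMATE_VARS.index(covariate)] += delta
            c2 = _dc_replace(c, climate=clim)
        elif covariate == "elevation":
            c2 = _dc_replace(c, elevation=c.elevation + delta)
        else:
            raise ValueError(f"unknown covariate {covariate!r}")
        p0 = choice_probabilities(c, params, config).p_joint
        p1 = choice_probabilities(c2, params, config).p_joint
        for key in p0:
            acc[key] = acc.get(key, 0.0) + (p1[key] - p0[key])
    return {k: v / len(ctxs) for k, v in acc.items()}
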