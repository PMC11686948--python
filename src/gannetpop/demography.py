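"""Demographic rate functions and the one-step metapopulation update.

The process model tracks breeders ``P_{n,t}`` (AOS) and a stage-structured
pre-breeder pool per colony.  Fecundity responds to climate through a
linear/quadratic logit predictor with shared annual noise; recruitment is
density dependent, dampened by whichever of the terrestrial (``nu_n``) or
marine (``eta_{n,t}``) coefficient is larger, i.e. by the smaller implied
carrying capacity.  Adults survive with probability ``phi_ad`` except in
2022, when the HPAI outbreak reduces survival at affected colonies.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

from .modelspec import ModelSpec
from .params import (
    HPAI_STATUSES,
    HPAI_SURVIVAL_AFFECTED,
    HPAI_YEAR,
    MAX_ADULT_SURVIVAL,
    ColonyState,
    DemographicParams,
)

__all__ = [
    "fecundity_rate",
    "marine_dd",
    "terrestrial_dd",
    "recruitment_rate",
    "marine_carrying_capacity",
    "capacity_dominance",
    "hpai_survival",
    "step_metapopulation",
]


def _linear_predictor(x: dict, intercept, lin: dict, quad: dict, spec_terms) -> float:
    """Evaluate intercept + sum(lin*x) - sum(quad*x^2) over the spec's terms."""
    total = np.asarray(intercept, dtype=float)
    for cov, order in spec_terms:
        if cov not in x:
            raise KeyError(f"covariate {cov!r} required by the model spec is missing")
        xv = np.asarray(x[cov], dtype=float)
        if order == 1:
            total = total + lin.get(cov, 0.0) * xv
        else:
            total = total - quad.get(cov, 0.0) * xv**2
    return total


def fecundity_rate(x: dict, params: DemographicParams, spec: ModelSpec, eps_t: float = 0.0):
    """Fecundity b (chicks per nest) from standardized covariates.

    ``logit b = alpha0 + sum_i alpha_lin[i] x_i - alpha_quad[i] x_i^2 + eps_t``;
    quadratic magnitudes carry their negative sign here, so climate optima
    are downward parabolas.  ``eps_t`` is the shared annual noise.
    """
    lp = _linear_predictor(x, params.alpha0, params.alpha_lin, params.alpha_quad,
                           spec.fecundity_terms)
    return expit(lp + eps_t)


def marine_dd(x: dict, params: DemographicParams, spec: ModelSpec):
    """Marine density-dependence coefficient eta in (0,1); no noise term."""
    lp = _linear_predictor(x, params.beta0, params.beta_lin, params.beta_quad,
                           spec.recruitment_terms)
    return expit(lp)


def terrestrial_dd(K, params: DemographicParams):
    """Terrestrial density-dependence coefficient nu = (alpha - logit(re)) / K."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("K must be positive")
    return (params.alpha_const - logit(params.re)) / K


def recruitment_rate(P, nu, eta, params: DemographicParams):
    """Recruitment probability r = logit^{-1}(alpha - max(nu, eta) * P).

    Practically 1 at P = 0 (alpha large), strictly decreasing in P, and
    exactly ``re`` when P equals the binding carrying capacity.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("colony size P must be non-negative")
    return expit(params.alpha_const - np.maximum(nu, eta) * P)


def marine_carrying_capacity(eta, params: DemographicParams):
    """Marine carrying capacity C = (alpha - logit(re)) / eta (AOS)."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta <= 0):
        raise ValueError("eta must be positive")
    return (params.alpha_const - logit(params.re)) / eta


def capacity_dominance(C, K):
    """Signed capacity difference C - K and the regulation regime label.

    Positive differences mean the terrestrial capacity is the smaller,
    binding one ("terrestrial" regulation); ties are labelled terrestrial.
    """
    C = np.asarray(C, dtype=float)
    K = np.asarray(K, dtype=float)
    diff = C - K
    labels = np.where(diff >= 0, "terrestrial", "marine")
    if diff.ndim == 0:
        return float(diff), str(labels)
    return diff, labels


def hpai_survival(status, params: DemographicParams, rng: np.random.Generator | None = None):
    """Adult survival applied in the 2022 HPAI outbreak year.

    Affected colonies get the measured 0.455; the unaffected colony keeps
    the regular survival; unknown-status colonies draw from
    Uniform(0.455, 0.94) (in inference this is a free parameter with the
    same prior).
    """
    if isinstance(status, str):
        status = [status]
        scalar = True
    else:
        scalar = False
    out = np.empty(len(status), dtype=float)
    for i, s in enumerate(status):
        if s == "affected":
            out[i] = HPAI_SURVIVAL_AFFECTED
        elif s == "unaffected":
            out[i] = params.phi_ad
        elif s == "unknown":
            if rng is None:
                raise ValueError("rng required to draw survival for unknown HPAI status")
            out[i] = rng.uniform(HPAI_SURVIVAL_AFFECTED, MAX_ADULT_SURVIVAL)
        else:
            raise ValueError(f"unknown HPAI status {s!r}; expected one of {HPAI_STATUSES}")
    return float(out[0]) if scalar else out


def movement_weights(P, rho: float) -> np.ndarray:
    """Conspecific-attraction kernel.

    Row n gives the distribution of recruitment-age pre-breeders born at
    colony n over target colonies m: weight ``rho * P_n`` for the natal
    colony, ``P_m`` elsewhere, normalized per row.  If every colony is
    empty the pool stays at its natal colony.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    W = np.tile(P, (n, 1))
    W[np.diag_indices(n)] = rho * P
    rowsum = W.sum(axis=1, keepdims=True)
    out = np.where(rowsum > 0, W / np.where(rowsum > 0, rowsum, 1.0), np.eye(n))
    return out


def step_metapopulation(
    state: ColonyState,
    climate: dict,
    params: DemographicParams,
    spec: ModelSpec,
    rng: np.random.Generator | None = None,
    eps_t: float | None = None,
    hpai_status=None,
) -> ColonyState:
    """Advance the metapopulation one year (expected dynamics).

    Order of events within the year ``t -> t+1``:

    1. fecundity ``b_{n,t}`` from this year's climate (+ shared noise
       ``eps_t``, drawn from N(0, sigma_b) if not supplied);
    2. the oldest pre-breeder class survives with ``phi_juv`` and is
       redistributed over colonies by conspecific attraction
       (:func:`movement_weights`), then recruits with probability
       ``r_{m,t}`` evaluated at the target colony; failed recruits return
       to their natal pool and retry next year (until death);
    3. adults survive with ``phi_ad`` (HPAI override in 2022);
    4. younger pre-breeder classes age with survival ``phi_juv`` and the
       new cohort ``chick_pair_ratio * b * P`` enters class 1.

    ``climate`` maps covariate name -> per-colony array for ``state.year``.
    Abundances are expectations (non-negative reals); the only stochastic
    elements are ``eps_t`` and unknown-status HPAI survival draws.
    """
    n = state.n_colonies
    for v in climate.values():
        if np.asarray(v).shape not in ((), (n,)):
            raise ValueError("climate arrays must match the colony set of the state")
    x = {k: np.broadcast_to(np.asarray(v, dtype=float), (n,)) for k, v in climate.items()}

    if eps_t is None:
        eps_t = float(rng.normal(0.0, params.sigma_b)) if rng is not None else 0.0

    b = fecundity_rate(x, params, spec, eps_t)
    eta = marine_dd(x, params, spec)
    nu = terrestrial_dd(params.K, params)
    r = recruitment_rate(state.P, nu, eta, params)

    # survival of the year, with the 2022 HPAI shock on adults
    if state.year == HPAI_YEAR and hpai_status is not None:
        phi = np.asarray(hpai_survival(list(hpai_status), params, rng), dtype=float)
    else:
        phi = np.full(n, params.phi_ad)

    # recruitment-age pool: survivors of the oldest class, redistributed
    Q = params.phi_juv * state.J[:, -1]
    W = movement_weights(state.P, params.rho)
    arrivals = Q @ W                      # arrivals[m] = sum_n Q_n W[n, m]
    recruits = arrivals * r               # succeed at the target colony
    failed_back = (W * (1.0 - r)[None, :]).sum(axis=1) * Q  # return to natal pool

    P_next = phi * state.P + recruits
    J_next = np.empty_like(state.J)
    # the new cohort takes its first-year survival at creation; failed
    # recruits already survived this year inside Q and simply retry
    J_next[:, 0] = params.phi_juv * params.chick_pair_ratio * b * state.P
    if params.a_first > 1:
        J_next[:, 1:] = params.phi_juv * state.J[:, :-1]
    J_next[:, -1] += failed_back

    return ColonyState(P_next, J_next, state.year + 1)
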