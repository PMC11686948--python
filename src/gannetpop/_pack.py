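"""Flat-vector packing of parameters and latents for the numba kernels.

The engine works on one flat ``theta`` vector (see ``_engine``); this
module translates between that vector and the high-level containers
(:class:`~gannetpop.params.DemographicParams`, model specs, eps series),
and offers a friendly wrapper around the trajectory kernel.
"""

from __future__ import annotations

import math

import numpy as np

from . import _engine as eng
from .modelspec import ModelSpec
from .params import COVARIATES, DemographicParams

_COV_IDX = {c: i for i, c in enumerate(COVARIATES)}


def spec_arrays(spec: ModelSpec):
    """(fec_cov, fec_quad, rec_cov, rec_quad) index/flag arrays for the engine."""
    fec = spec.covariates("fecundity")
    rec = spec.covariates("recruitment")
    fec_cov = np.array([_COV_IDX[c] for c, _ in fec], dtype=np.int64)
    fec_quad = np.array([1 if q else 0 for _, q in fec], dtype=np.int64)
    rec_cov = np.array([_COV_IDX[c] for c, _ in rec], dtype=np.int64)
    rec_quad = np.array([1 if q else 0 for _, q in rec], dtype=np.int64)
    return fec_cov, fec_quad, rec_cov, rec_quad


def build_layout(n_colonies: int, n_steps: int, spec: ModelSpec,
                 a_first: int = 5, hpai_t: int = -1, n_hpai: int = 0) -> np.ndarray:
    """Engine layout vector; ``n_steps`` is the number of yearly transitions."""
    nf = len(spec.covariates("fecundity"))
    nr = len(spec.covariates("recruitment"))
    lay = np.zeros(eng.L_SIZE, dtype=np.int64)
    lay[eng.L_N] = n_colonies
    lay[eng.L_T] = n_steps
    lay[eng.L_A] = a_first
    lay[eng.L_NF] = nf
    lay[eng.L_NR] = nr
    lay[eng.L_OFF_FLIN] = 1
    lay[eng.L_OFF_FQUAD] = 1 + nf
    lay[eng.L_OFF_BETA0] = 1 + 2 * nf
    lay[eng.L_OFF_RLIN] = 2 + 2 * nf
    lay[eng.L_OFF_RQUAD] = 2 + 2 * nf + nr
    lay[eng.L_OFF_SIGB] = 2 + 2 * nf + 2 * nr
    lay[eng.L_OFF_SIGOBS] = lay[eng.L_OFF_SIGB] + 1
    lay[eng.L_OFF_HPAI] = lay[eng.L_OFF_SIGOBS] + 1
    lay[eng.L_NHPAI] = n_hpai
    lay[eng.L_OFF_LOGK] = lay[eng.L_OFF_HPAI] + n_hpai
    lay[eng.L_OFF_LOGP0] = lay[eng.L_OFF_LOGK] + n_colonies
    lay[eng.L_OFF_EPS] = lay[eng.L_OFF_LOGP0] + n_colonies
    lay[eng.L_HPAI_T] = hpai_t
    return lay


def theta_size(layout: np.ndarray) -> int:
    return int(layout[eng.L_OFF_EPS] + layout[eng.L_T])


def fixed_vector(params: DemographicParams) -> np.ndarray:
    fx = np.zeros(eng.F_SIZE)
    fx[eng.F_PHI_AD] = params.phi_ad
    fx[eng.F_PHI_JUV] = params.phi_juv
    fx[eng.F_ALPHA] = params.alpha_const
    fx[eng.F_LOGIT_RE] = math.log(params.re / (1.0 - params.re))
    fx[eng.F_RHO] = params.rho
    fx[eng.F_CPR] = params.chick_pair_ratio
    return fx


def hyper_vector(logP0_mean: float = math.log(500.0), logP0_sd: float = 3.0,
                 intercept_sd: float = 10.0, lin_sd: float = 1.0,
                 k_cv: float = 0.2, sig_sd: float = 1.0) -> np.ndarray:
    """Prior hyperparameters; ``k_cv`` is the CV of the log-normal K prior."""
    hy = np.zeros(eng.P_SIZE)
    hy[eng.P_INT_SD] = intercept_sd
    hy[eng.P_LIN_SD] = lin_sd
    hy[eng.P_SDLOGK] = math.sqrt(math.log(1.0 + k_cv**2))
    hy[eng.P_LOGP0_MEAN] = logP0_mean
    hy[eng.P_LOGP0_SD] = logP0_sd
    hy[eng.P_SIG_SD] = sig_sd
    hy[eng.P_HPAI_LO] = 0.455
    hy[eng.P_HPAI_HI] = 0.94
    return hy


def pack_theta(params: DemographicParams, spec: ModelSpec, layout: np.ndarray,
               eps: np.ndarray | None = None, logP0: np.ndarray | None = None,
               hpai_phi: np.ndarray | None = None) -> np.ndarray:
    """Flatten parameter containers into an engine theta vector."""
    theta = np.zeros(theta_size(layout))
    theta[0] = params.alpha0
    fec = spec.covariates("fecundity")
    rec = spec.covariates("recruitment")
    for i, (cov, quad) in enumerate(fec):
        theta[layout[eng.L_OFF_FLIN] + i] = params.alpha_lin.get(cov, 0.0)
        if quad:
            theta[layout[eng.L_OFF_FQUAD] + i] = params.alpha_quad.get(cov, 0.0)
    theta[layout[eng.L_OFF_BETA0]] = params.beta0
    for i, (cov, quad) in enumerate(rec):
        theta[layout[eng.L_OFF_RLIN] + i] = params.beta_lin.get(cov, 0.0)
        if quad:
            theta[layout[eng.L_OFF_RQUAD] + i] = params.beta_quad.get(cov, 0.0)
    theta[layout[eng.L_OFF_SIGB]] = params.sigma_b
    theta[layout[eng.L_OFF_SIGOBS]] = params.sigma_obs
    if hpai_phi is not None:
        theta[layout[eng.L_OFF_HPAI]:layout[eng.L_OFF_HPAI] + layout[eng.L_NHPAI]] = hpai_phi
    theta[layout[eng.L_OFF_LOGK]:layout[eng.L_OFF_LOGK] + layout[eng.L_N]] = np.log(params.K)
    if logP0 is not None:
        theta[layout[eng.L_OFF_LOGP0]:layout[eng.L_OFF_LOGP0] + layout[eng.L_N]] = logP0
    if eps is not None:
        theta[layout[eng.L_OFF_EPS]:layout[eng.L_OFF_EPS] + layout[eng.L_T]] = eps
    return theta


def params_from_theta(theta: np.ndarray, layout: np.ndarray, spec: ModelSpec,
                      template: DemographicParams) -> DemographicParams:
    """Rebuild a DemographicParams from a theta vector (fixed fields from template)."""
    fec = spec.covariates("fecundity")
    rec = spec.covariates("recruitment")
    alpha_lin, alpha_quad, beta_lin, beta_quad = {}, {}, {}, {}
    for i, (cov, quad) in enumerate(fec):
        alpha_lin[cov] = float(theta[layout[eng.L_OFF_FLIN] + i])
        if quad:
            alpha_quad[cov] = float(theta[layout[eng.L_OFF_FQUAD] + i])
    for i, (cov, quad) in enumerate(rec):
        beta_lin[cov] = float(theta[layout[eng.L_OFF_RLIN] + i])
        if quad:
            beta_quad[cov] = float(theta[layout[eng.L_OFF_RQUAD] + i])
    K = np.exp(theta[layout[eng.L_OFF_LOGK]:layout[eng.L_OFF_LOGK] + layout[eng.L_N]])
    return template.with_(
        alpha0=float(theta[0]), alpha_lin=alpha_lin, alpha_quad=alpha_quad,
        beta0=float(theta[layout[eng.L_OFF_BETA0]]), beta_lin=beta_lin,
        beta_quad=beta_quad, sigma_b=float(theta[layout[eng.L_OFF_SIGB]]),
        sigma_obs=float(theta[layout[eng.L_OFF_SIGOBS]]), K=K,
    )


def sampled_indices(layout: np.ndarray) -> np.ndarray:
    """Coordinates swept by the sampler (inactive quadratic slots excluded).

    Quadratic slots are active exactly where the model structure has a
    quadratic term; the spec arrays carry those flags, so callers filter
    with :func:`spec_arrays`.  Here we return all structurally present
    coordinates; use ``mask_quads`` to drop inactive ones.
    """
    return np.arange(theta_size(layout), dtype=np.int64)


def active_indices(layout: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Indices of sampled coordinates for this model structure."""
    _, fec_quad, _, rec_quad = spec_arrays(spec)
    keep = np.ones(theta_size(layout), dtype=bool)
    for i, q in enumerate(fec_quad):
        if q == 0:
            keep[layout[eng.L_OFF_FQUAD] + i] = False
    for i, q in enumerate(rec_quad):
        if q == 0:
            keep[layout[eng.L_OFF_RQUAD] + i] = False
    return np.flatnonzero(keep).astype(np.int64)


def coord_tstart(layout: np.ndarray) -> np.ndarray:
    """First transition year each coordinate can alter (sampler speed-up).

    eps_t only affects the trajectory from year t; sigma_b touches only
    the prior and sigma_obs only the observation density; the 2022
    survival parameters only matter from the HPAI year on.  Everything
    else forces a full re-simulation (0).
    """
    ts = np.zeros(theta_size(layout), dtype=np.int64)
    ts[layout[eng.L_OFF_SIGB]] = eng.TS_PRIOR_ONLY
    ts[layout[eng.L_OFF_SIGOBS]] = eng.TS_OBS_ONLY
    for k in range(layout[eng.L_NHPAI]):
        ts[layout[eng.L_OFF_HPAI] + k] = max(layout[eng.L_HPAI_T], 0)
    for t in range(layout[eng.L_T]):
        ts[layout[eng.L_OFF_EPS] + t] = t
    return ts


def hpai_arrays(statuses, n_colonies: int):
    """(code, slot, n_unknown) arrays from per-colony status strings.

    Codes: 0 affected, 1 unaffected, 2 unknown; ``slot`` numbers the
    unknown-status colonies (−1 elsewhere).
    """
    code = np.zeros(n_colonies, dtype=np.int64)
    slot = np.full(n_colonies, -1, dtype=np.int64)
    k = 0
    for n, s in enumerate(statuses):
        if s == "affected":
            code[n] = 0
        elif s == "unaffected":
            code[n] = 1
        elif s == "unknown":
            code[n] = 2
            slot[n] = k
            k += 1
        else:
            raise ValueError(f"unknown HPAI status {s!r}")
    return code, slot, k


_NO_HPAI = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))


def simulate_trajectory(params: DemographicParams, spec: ModelSpec, X: np.ndarray,
                        eps: np.ndarray, P0: np.ndarray, J0: np.ndarray | None = None,
                        hpai_t: int = -1, hpai_statuses=None,
                        hpai_phi: np.ndarray | None = None):
    """Deterministic trajectory from explicit initial state.

    ``X`` is (T, N, 5) standardized covariates; returns
    ``(P, J_final, bmat, etamat)``.  If ``J0`` is None the pre-breeder
    pipeline starts at quasi-equilibrium for the year-0 fecundity.
    """
    T, N, _ = X.shape
    if eps.shape[0] != T:
        raise ValueError("eps must have one entry per transition year")
    if hpai_statuses is not None:
        code, slot, n_unknown = hpai_arrays(hpai_statuses, N)
    else:
        code = np.zeros(N, dtype=np.int64)
        slot = np.full(N, -1, dtype=np.int64)
        n_unknown = 0
    layout = build_layout(N, T, spec, params.a_first, hpai_t=hpai_t, n_hpai=n_unknown)
    theta = pack_theta(params, spec, layout, eps=eps, logP0=np.log(np.maximum(P0, 1e-12)),
                       hpai_phi=hpai_phi)
    fixed = fixed_vector(params)
    fc, fq, rc, rq = spec_arrays(spec)
    if J0 is None:
        # equilibrium init handled inside the kernel (use_state=0, P0 via theta)
        P, J, bmat, etamat = eng.simulate(theta, layout, fixed, X, fc, fq, rc, rq,
                                          code, slot, np.zeros(1), np.zeros((1, 1)), 0)
    else:
        P, J, bmat, etamat = eng.simulate(theta, layout, fixed, X, fc, fq, rc, rq,
                                          code, slot, np.asarray(P0, dtype=float),
                                          np.asarray(J0, dtype=float), 1)
    return P, J, bmat, etamat
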