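"""Bayesian fitting of the state-space metapopulation model.

The observation model combines log-normal census errors on Apparently
Occupied Sites and binomial fecundity records (chicks out of monitored
nests).  Priors follow the published structure: standard-normal priors
on linear climate coefficients, unit-rate gamma priors enforcing the
sign constraints of downward-parabola terms, expert-elicited log-normal
priors on terrestrial carrying capacities, and a Uniform(0.455, 0.94)
prior on 2022 adult survival at colonies of unknown HPAI status.

Sampling is adaptive random-walk Metropolis-within-Gibbs over the model
parameters and the latent degrees of freedom of the process (initial log
colony sizes and the shared annual fecundity deviations); convergence is
monitored with the Gelman–Rubin potential scale reduction factor and
models are ranked by DIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logit

from . import _engine as eng
from . import _pack as pk
from .modelspec import ModelSpec, enumerate_models  # noqa: F401  (re-export)
from .params import COVARIATES, HPAI_YEAR, DemographicParams
from .covariates import ClimateSeries

RHAT_THRESHOLD = 1.1


# ---------------------------------------------------------------------------
# data preparation

@dataclass
class FitData:
    """Observed data and climate aligned on a (colony, year) grid."""

    colonies: list
    years: np.ndarray              # calendar years of the states, length T+1
    X: np.ndarray                  # (T, N, 5) standardized covariates
    census: pd.DataFrame
    fecundity: pd.DataFrame
    K_expert: np.ndarray
    hpai_statuses: list | None = None
    # engine arrays
    cobs_t: np.ndarray = field(default=None, repr=False)
    cobs_n: np.ndarray = field(default=None, repr=False)
    cobs_logy: np.ndarray = field(default=None, repr=False)
    fobs_t: np.ndarray = field(default=None, repr=False)
    fobs_n: np.ndarray = field(default=None, repr=False)
    fobs_nests: np.ndarray = field(default=None, repr=False)
    fobs_chicks: np.ndarray = field(default=None, repr=False)
    fobs_lgconst: np.ndarray = field(default=None, repr=False)

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    @property
    def n_steps(self) -> int:
        return len(self.years) - 1

    @property
    def hpai_t(self) -> int:
        """Transition index of the 2022 HPAI year, -1 if outside the window."""
        idx = np.flatnonzero(self.years[:-1] == HPAI_YEAR)
        return int(idx[0]) if idx.size else -1


def census_log_observed(counts) -> np.ndarray:
    """log(count), with zero counts mapped to log(0.5)."""
    counts = np.asarray(counts, dtype=float)
    return np.log(np.where(counts > 0, counts, 0.5))


def prepare_data(census: pd.DataFrame, fecundity: pd.DataFrame,
                 climate: ClimateSeries, colonies, years, K_expert,
                 hpai_statuses=None, scenario: str = "hindcast") -> FitData:
    """Validate and align the inputs for one fitting window.

    ``years`` are the calendar years of the latent states (inclusive
    range); census rows outside it or naming unknown colonies are
    errors, as are fecundity rows with chicks > nests.
    """
    colonies = list(colonies)
    years = np.asarray(sorted(years), dtype=int)
    if not np.all(np.diff(years) == 1):
        raise ValueError("the fitting window must be contiguous years")
    col_pos = {c: i for i, c in enumerate(colonies)}
    year_pos = {int(y): i for i, y in enumerate(years)}

    for df, name, cols in ((census, "census", {"colony_id", "year", "aos_count"}),
                           (fecundity, "fecundity", {"colony_id", "year", "nests", "chicks"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
        bad = ~df.colony_id.isin(col_pos)
        if bad.any():
            raise ValueError(f"{name} row {df.index[bad][0]}: unknown colony "
                             f"{df.loc[bad, 'colony_id'].iloc[0]!r}")
        bad = ~df.year.isin(year_pos)
        if bad.any():
            raise ValueError(f"{name} row {df.index[bad][0]}: year "
                             f"{df.loc[bad, 'year'].iloc[0]} outside the window")
    neg = census.aos_count < 0
    if neg.any():
        raise ValueError(f"census row {census.index[neg][0]}: negative count")
    bad = fecundity.chicks > fecundity.nests
    if bad.any():
        raise ValueError(f"fecundity row {fecundity.index[bad][0]}: chicks > nests")
    if (fecundity.year.map(year_pos) >= len(years) - 1).any():
        raise ValueError("fecundity observations must precede the final state year")

    X = climate.to_array(scenario, colonies, years[:-1])
    K_expert = np.asarray(K_expert, dtype=float)
    if K_expert.shape != (len(colonies),):
        raise ValueError("K_expert must give one value per colony")

    n = fecundity.nests.to_numpy(dtype=float)
    c = fecundity.chicks.to_numpy(dtype=float)
    lgconst = gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)

    return FitData(
        colonies=colonies, years=years, X=X, census=census.copy(),
        fecundity=fecundity.copy(), K_expert=K_expert, hpai_statuses=hpai_statuses,
        cobs_t=census.year.map(year_pos).to_numpy(dtype=np.int64),
        cobs_n=census.colony_id.map(col_pos).to_numpy(dtype=np.int64),
        cobs_logy=census_log_observed(census.aos_count),
        fobs_t=fecundity.year.map(year_pos).to_numpy(dtype=np.int64),
        fobs_n=fecundity.colony_id.map(col_pos).to_numpy(dtype=np.int64),
        fobs_nests=n, fobs_chicks=c, fobs_lgconst=lgconst,
    )


def _engine_args(data: FitData, spec: ModelSpec, params: DemographicParams):
    """Layout, fixed/hyper vectors and data arrays for the kernels."""
    if data.hpai_statuses is not None and data.hpai_t >= 0:
        code, slot, n_unknown = pk.hpai_arrays(data.hpai_statuses, data.n_colonies)
    else:
        code = np.zeros(data.n_colonies, dtype=np.int64)
        slot = np.full(data.n_colonies, -1, dtype=np.int64)
        n_unknown = 0
    layout = pk.build_layout(data.n_colonies, data.n_steps, spec, params.a_first,
                             hpai_t=data.hpai_t, n_hpai=n_unknown)
    fixed = pk.fixed_vector(params)
    hyper = pk.hyper_vector()
    fc, fq, rc, rq = pk.spec_arrays(spec)
    return layout, fixed, hyper, fc, fq, rc, rq, code, slot


def log_likelihood(theta: np.ndarray, data: FitData, spec: ModelSpec,
                   params: DemographicParams) -> float:
    """Observation log-likelihood at one point of the theta space."""
    layout, fixed, _, fc, fq, rc, rq, code, slot = _engine_args(data, spec, params)
    return float(eng.log_likelihood(
        theta, layout, fixed, data.X, fc, fq, rc, rq, code, slot,
        data.cobs_t, data.cobs_n, data.cobs_logy, data.fobs_t, data.fobs_n,
        data.fobs_nests, data.fobs_chicks, data.fobs_lgconst))


def log_prior(theta: np.ndarray, data: FitData, spec: ModelSpec,
              params: DemographicParams) -> float:
    """Prior log-density (−inf outside the support)."""
    layout, fixed, hyper, fc, fq, rc, rq, code, slot = _engine_args(data, spec, params)
    return float(eng.log_prior(theta, layout, fixed, hyper, fq, rq,
                               np.log(data.K_expert)))


# ---------------------------------------------------------------------------
# diagnostics

def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor, per parameter.

    ``chains`` has shape (m, n, p) with m >= 2 chains of n draws.  The
    classic (non-split) estimator: with within-chain variance W and
    between-chain variance B, R = sqrt(((n-1)/n W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, _ = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    means = chains.mean(axis=1)                     # (m, p)
    W = chains.var(axis=1, ddof=1).mean(axis=0)     # (p,)
    B = n * means.var(axis=0, ddof=1)               # (p,)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W > 0, rhat, 1.0)


# ---------------------------------------------------------------------------
# MCMC driver

@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings; full-study-scale defaults, scalable for desk tests."""

    chains: int = 4
    iters: int = 100_000
    burnin: int = 15_000
    max_burnin: int = 215_000
    thin: int = 200
    seed: int = 1

    def __post_init__(self):
        if min(self.chains, self.iters, self.burnin, self.thin) <= 0:
            raise ValueError("all MCMC settings must be positive")
        if self.burnin >= self.iters:
            raise ValueError("burn-in must be shorter than the chain")


@dataclass
class MCMCResult:
    """Raw draws plus everything needed to summarize them."""

    draws: np.ndarray             # (chains, n_keep, n_theta)
    loglik: np.ndarray            # (chains, n_keep)
    layout: np.ndarray
    spec: ModelSpec
    template: DemographicParams
    data: FitData
    param_names: list
    sampled: np.ndarray
    settings: MCMCSettings

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def _param_names(layout, spec: ModelSpec, data: FitData) -> list:
    names = [""] * pk.theta_size(layout)
    names[0] = "alpha0"
    for i, (cov, quad) in enumerate(spec.covariates("fecundity")):
        names[layout[eng.L_OFF_FLIN] + i] = f"alpha_{cov}"
        names[layout[eng.L_OFF_FQUAD] + i] = f"alpha_{cov}_sq"
    names[layout[eng.L_OFF_BETA0]] = "beta0"
    for i, (cov, quad) in enumerate(spec.covariates("recruitment")):
        names[layout[eng.L_OFF_RLIN] + i] = f"beta_{cov}"
        names[layout[eng.L_OFF_RQUAD] + i] = f"beta_{cov}_sq"
    names[layout[eng.L_OFF_SIGB]] = "sigma_b"
    names[layout[eng.L_OFF_SIGOBS]] = "sigma_obs"
    k = 0
    if data.hpai_statuses is not None:
        for c, s in zip(data.colonies, data.hpai_statuses):
            if s == "unknown" and layout[eng.L_NHPAI] > 0:
                names[layout[eng.L_OFF_HPAI] + k] = f"phi_hpai_{c}"
                k += 1
    for n, c in enumerate(data.colonies):
        names[layout[eng.L_OFF_LOGK] + n] = f"logK_{c}"
        names[layout[eng.L_OFF_LOGP0] + n] = f"logP0_{c}"
    for t in range(layout[eng.L_T]):
        names[layout[eng.L_OFF_EPS] + t] = f"eps_{data.years[t]}"
    return names


def _initial_theta(data: FitData, spec: ModelSpec, params: DemographicParams,
                   layout, rng: np.random.Generator) -> np.ndarray:
    """Data-informed, per-chain jittered starting point."""
    theta = np.zeros(pk.theta_size(layout))
    if len(data.fobs_nests):
        bbar = float(np.clip(data.fobs_chicks.sum() / data.fobs_nests.sum(), 0.02, 0.98))
    else:
        bbar = 0.7
    theta[0] = logit(bbar) + 0.3 * rng.normal()
    for i, (cov, quad) in enumerate(spec.covariates("fecundity")):
        theta[layout[eng.L_OFF_FLIN] + i] = (abs(rng.normal(0, 0.3)) + 0.05 if quad
                                             else rng.normal(0, 0.3))
        if quad:
            theta[layout[eng.L_OFF_FQUAD] + i] = abs(rng.normal(0, 0.3)) + 0.05
    # start the marine capacity well above the observed colony sizes
    cmax = max(data.census.aos_count.max(), data.K_expert.max())
    eta0 = (params.alpha_const - logit(params.re)) / (10.0 * cmax)
    theta[layout[eng.L_OFF_BETA0]] = logit(min(eta0, 0.5)) + 0.3 * rng.normal()
    for i, (cov, quad) in enumerate(spec.covariates("recruitment")):
        theta[layout[eng.L_OFF_RLIN] + i] = (abs(rng.normal(0, 0.3)) + 0.05 if quad
                                             else rng.normal(0, 0.3))
        if quad:
            theta[layout[eng.L_OFF_RQUAD] + i] = abs(rng.normal(0, 0.3)) + 0.05
    theta[layout[eng.L_OFF_SIGB]] = 0.3 * math.exp(0.3 * rng.normal())
    theta[layout[eng.L_OFF_SIGOBS]] = 0.2 * math.exp(0.3 * rng.normal())
    for k in range(layout[eng.L_NHPAI]):
        theta[layout[eng.L_OFF_HPAI] + k] = rng.uniform(0.5, 0.9)
    theta[layout[eng.L_OFF_LOGK]:layout[eng.L_OFF_LOGK] + data.n_colonies] = (
        np.log(data.K_expert) + 0.1 * rng.normal(size=data.n_colonies))
    first_obs = np.full(data.n_colonies, np.nan)
    for c, y, v in zip(data.cobs_n, data.cobs_t, data.cobs_logy):
        if np.isnan(first_obs[c]):
            first_obs[c] = v
    fallback = np.log(data.K_expert / 10.0)
    logp0 = np.where(np.isnan(first_obs), fallback, first_obs)
    theta[layout[eng.L_OFF_LOGP0]:layout[eng.L_OFF_LOGP0] + data.n_colonies] = (
        logp0 + 0.2 * rng.normal(size=data.n_colonies))
    theta[layout[eng.L_OFF_EPS]:layout[eng.L_OFF_EPS] + data.n_steps] = (
        0.05 * rng.normal(size=data.n_steps))
    return theta


def run_mcmc(data: FitData, spec: ModelSpec, params: DemographicParams | None = None,
             settings: MCMCSettings = MCMCSettings()) -> MCMCResult:
    """Fit one model structure; returns draws plus bookkeeping.

    ``params`` supplies the fixed natural-history constants (survival,
    age of first breeding, re, alpha, rho); estimated quantities in it
    are ignored.  Chains c = 0..C-1 are seeded ``settings.seed + c``.
    """
    if params is None:
        params = DemographicParams(K=data.K_expert)
    layout, fixed, hyper, fc, fq, rc, rq, code, slot = _engine_args(data, spec, params)
    sampled = pk.active_indices(layout, spec)
    names = _param_names(layout, spec, data)

    scales0 = np.full(pk.theta_size(layout), 0.1)
    n_keep = (settings.iters - settings.burnin) // settings.thin
    draws = np.empty((settings.chains, n_keep, pk.theta_size(layout)))
    lls = np.empty((settings.chains, n_keep))
    logK_exp = np.log(data.K_expert)
    for c in range(settings.chains):
        rng = np.random.default_rng(settings.seed + c)
        theta0 = _initial_theta(data, spec, params, layout, rng)
        d, l, _, _ = eng.run_chain(
            theta0, sampled, pk.coord_tstart(layout), scales0,
            settings.iters, settings.burnin,
            settings.thin, (settings.seed + c) % (2**31 - 1),
            layout, fixed, hyper, data.X, fc, fq, rc, rq, code, slot, logK_exp,
            data.cobs_t, data.cobs_n, data.cobs_logy, data.fobs_t, data.fobs_n,
            data.fobs_nests, data.fobs_chicks, data.fobs_lgconst)
        draws[c] = d
        lls[c] = l
    return MCMCResult(draws=draws, loglik=lls, layout=layout, spec=spec,
                      template=params, data=data, param_names=names,
                      sampled=sampled, settings=settings)


# ---------------------------------------------------------------------------
# summaries, DIC, selection

@dataclass
class PosteriorSummary:
    """Posterior medians, 95% CIs, convergence diagnostics and DIC."""

    params: pd.DataFrame          # name, median, lo95, hi95, rhat
    latent: pd.DataFrame          # colony, year, median, lo95, hi95, sd
    dic: float
    dbar: float
    pd_: float
    converged: bool
    max_rhat: float
    model_id: str

    def ci(self, name: str) -> tuple:
        row = self.params.set_index("name").loc[name]
        return float(row.lo95), float(row.hi95)

    def median(self, name: str) -> float:
        return float(self.params.set_index("name").loc[name, "median"])


def dic(result: MCMCResult) -> tuple:
    """(DIC, Dbar, pD) with the deviance focused on the observation level.

    Deviance D = −2 log p(data | params, latents); ``Dbar`` averages D
    over the draws and ``pD = Dbar − D(posterior mean)`` plugs in the
    posterior mean of all sampled quantities.  pD can come out negative
    for badly non-normal posteriors; it is reported as computed.
    """
    lls = result.loglik.ravel()
    if lls.size < 30:
        raise ValueError(f"need at least 30 retained draws for DIC, have {lls.size}")
    dbar = float(np.mean(-2.0 * lls))
    theta_bar = result.flat().mean(axis=0)
    ll_hat = log_likelihood(theta_bar, result.data, result.spec, result.template)
    pd_ = dbar - (-2.0 * ll_hat)
    if pd_ < 0:
        import warnings

        warnings.warn(f"negative effective parameter count pD = {pd_:.2f} "
                      "(posterior far from normal); DIC reported as computed",
                      RuntimeWarning, stacklevel=2)
    return dbar + pd_, dbar, pd_


def summarize(result: MCMCResult, latent_draw_cap: int = 400) -> PosteriorSummary:
    """Medians, central 95% intervals, R-hat per sampled coordinate, DIC.

    Latent colony-size posteriors are obtained by pushing draws through
    the deterministic process (capped at ``latent_draw_cap`` draws).
    """
    flat = result.flat()
    med = np.median(flat, axis=0)
    lo = np.percentile(flat, 2.5, axis=0)
    hi = np.percentile(flat, 97.5, axis=0)
    rhat_all = np.full(flat.shape[1], np.nan)
    rhat_all[result.sampled] = gelman_rubin(result.draws[:, :, result.sampled])
    ptab = pd.DataFrame({"name": result.param_names, "median": med,
                         "lo95": lo, "hi95": hi, "rhat": rhat_all})
    ptab = ptab[ptab.name != ""].reset_index(drop=True)

    max_rhat = float(np.nanmax(rhat_all))
    converged = bool(max_rhat < RHAT_THRESHOLD)

    data, spec, layout = result.data, result.spec, result.layout
    fixed = pk.fixed_vector(result.template)
    fc, fq, rc, rq = pk.spec_arrays(spec)
    if data.hpai_statuses is not None and data.hpai_t >= 0:
        code, slot, _ = pk.hpai_arrays(data.hpai_statuses, data.n_colonies)
    else:
        code = np.zeros(data.n_colonies, dtype=np.int64)
        slot = np.full(data.n_colonies, -1, dtype=np.int64)
    sel = np.linspace(0, flat.shape[0] - 1, min(latent_draw_cap, flat.shape[0])).astype(int)
    Ps = np.empty((sel.size, data.n_steps + 1, data.n_colonies))
    for k, idx in enumerate(sel):
        P, _, _, _ = eng.simulate(flat[idx], layout, fixed, data.X, fc, fq, rc, rq,
                                  code, slot, np.zeros(1), np.zeros((1, 1)), 0)
        Ps[k] = P
    rows = []
    for n, colony in enumerate(data.colonies):
        for iy, y in enumerate(data.years):
            v = Ps[:, iy, n]
            rows.append((colony, int(y), float(np.median(v)),
                         float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)),
                         float(np.std(v))))
    latent = pd.DataFrame(rows, columns=["colony", "year", "median", "lo95", "hi95", "sd"])

    d, dbar, pd_ = dic(result)
    return PosteriorSummary(params=ptab, latent=latent, dic=d, dbar=dbar, pd_=pd_,
                            converged=converged, max_rhat=max_rhat,
                            model_id=spec.id)


def select_model(data: FitData, specs, params: DemographicParams | None = None,
                 settings: MCMCSettings = MCMCSettings()) -> pd.DataFrame:
    """Fit each candidate structure and rank by DIC.

    ΔDIC = DIC_null − DIC_model, so the best model has the highest ΔDIC
    and the lowest DIC.  Non-converged fits keep their DIC but are
    excluded from the "best" ranking (reported via the converged flag).
    """
    specs = list(specs)
    ids = [s.id for s in specs]
    if "m0.00" not in ids:
        raise ValueError("the candidate list must include the null model m0.00")
    rows = {}
    for spec in specs:
        res = run_mcmc(data, spec, params, settings)
        summ = summarize(res, latent_draw_cap=2)  # latents not needed here
        fterms = "+".join(f"{c}^2" if q else c for c, q in spec.covariates("fecundity")) or "-"
        rterms = "+".join(f"{c}^2" if q else c for c, q in spec.covariates("recruitment")) or "-"
        rows[spec.id] = dict(model=spec.id, fecundity=fterms, recruitment=rterms,
                             DIC=summ.dic, pD=summ.pd_, converged=summ.converged,
                             max_rhat=summ.max_rhat)
    dic_null = rows["m0.00"]["DIC"]
    tab = pd.DataFrame([rows[i] for i in ids])
    tab["dDIC"] = dic_null - tab["DIC"]
    tab = tab.sort_values("DIC", kind="stable").reset_index(drop=True)
    conv = tab[tab.converged]
    tab.attrs["best"] = (conv.model.iloc[0] if len(conv) else None)
    return tab
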