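"""Synthetic studies with the statistical structure the analysis assumes.

The generator emulates the study system end to end: a small network of
colonies along a latitudinal temperature gradient; two-century climate
series that split into a low-emission (SSP1) and a very-high-emission
(SSP5) future after 2014; latent colony trajectories driven by the same
process model the inference fits; sparse census counts with log-normal
observation error; and binomial fecundity records.  Default parameter
values for the climate-response coefficients are the posterior medians
of the published best-fitting model, so the synthetic system behaves
like the real one: an intermediate air-temperature optimum for fecundity
(some colonies sit above it, some below) and SST-dependent marine
carrying capacities that bind for the larger colonies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _pack as pk
from .covariates import ClimateSeries, standardize
from .modelspec import ModelSpec
from .params import COVARIATES, DemographicParams

#: model structure used to generate data by default: quadratic nsAT +
#: linear precipitation on fecundity, linear SST on recruitment.
DEFAULT_TRUE_SPEC = ModelSpec(
    id="m3.3^251",
    fecundity_terms=(("nsAT", 1), ("nsAT", 2), ("prec", 1)),
    recruitment_terms=(("SST", 1),),
)


def default_true_params(n_colonies: int = 6) -> DemographicParams:
    """Generating parameters: published best-model medians plus
    natural-history constants; terrestrial capacities span small
    terrestrially-regulated to large marine-regulated colonies."""
    K = np.geomspace(8_000, 250_000, n_colonies)
    return DemographicParams(
        alpha0=0.969,
        alpha_lin={"nsAT": 1.546, "prec": 0.139},
        alpha_quad={"nsAT": 0.848},
        beta0=-6.619,
        beta_lin={"SST": 0.881},
        sigma_b=0.3,
        sigma_obs=0.1,
        K=K,
    )


@dataclass
class SyntheticStudy:
    """One complete synthetic data set plus its generating truth."""

    params_true: DemographicParams
    spec_true: ModelSpec
    climate: ClimateSeries            # standardized; constants attached
    colonies: list
    years: np.ndarray                 # state years of the fitting window
    latent: pd.DataFrame              # colony, year, P (true latent sizes)
    eps_true: np.ndarray
    census: pd.DataFrame              # colony_id, year, aos_count
    fecundity: pd.DataFrame           # colony_id, year, nests, chicks
    hpai_status: dict
    seed: int
    latitudes: np.ndarray = field(default=None)
    J_final: np.ndarray = field(default=None, repr=False)
    bmat: np.ndarray = field(default=None, repr=False)

    def latent_matrix(self) -> np.ndarray:
        piv = self.latent.pivot(index="year", columns="colony", values="P")
        return piv[self.colonies].to_numpy()


def generate_climate(n_colonies: int = 6, years=(1900, 2100), seed: int = 0,
                     trend_nsat: float = 0.008, trend_sst: float = 0.006,
                     ssp1_extra: float = 1.0, ssp5_extra: float = 4.0,
                     ar_phi: float = 0.5, ar_sd: float = 0.45,
                     lat_range=(48.0, 71.0)) -> ClimateSeries:
    """Two-century colony-level covariate series with scenario divergence.

    Temperatures combine a latitude-dependent baseline (~10 °C of nsAT
    across the colony set), a linear historical warming trend
    (°C/year), AR(1) interannual noise, and post-2014 scenario paths:
    SSP1 adds ``ssp1_extra`` °C by 2100 with warming levelling off,
    SSP5 adds ``ssp5_extra`` °C accelerating.  SSP1 and SSP5 are
    identical to the hindcast through 2014 (shared noise innovations
    afterwards, so scenario contrasts are climate signal, not noise).
    The hindcast rows for 2015–2016 are the scenario mean, mirroring
    how fitting-window covariates are assembled from forecast fields.
    """
    rng = np.random.default_rng(seed)
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    T = yrs.size
    lats = np.linspace(lat_range[0], lat_range[1], n_colonies)

    def ar1(size):
        e = rng.normal(0.0, ar_sd, size=size)
        out = np.empty(size)
        out[0] = e[0] / np.sqrt(max(1.0 - ar_phi**2, 1e-12))
        for t in range(1, size):
            out[t] = ar_phi * out[t - 1] + e[t]
        return out

    # scenario warming anomaly relative to 2014, shared across colonies
    fut = np.clip(yrs - 2014, 0, None) / (2100 - 2014)
    anom1 = ssp1_extra * np.sin(0.5 * np.pi * np.minimum(fut * 1.6, 1.0))  # levels off
    anom5 = ssp5_extra * fut**1.5                                          # accelerates

    records = []
    for n in range(n_colonies):
        lat = lats[n]
        base = {
            "nsAT": 14.0 - 10.0 * (lat - lat_range[0]) / (lat_range[1] - lat_range[0]),
            "SST": 12.0 - 8.0 * (lat - lat_range[0]) / (lat_range[1] - lat_range[0]),
            "SLM": 35.2 - 0.02 * (lat - lat_range[0]),
            "nsWS": 7.5 + 0.03 * (lat - lat_range[0]),
            "prec": 65.0 + 0.5 * (lat - lat_range[0]),
        }
        hist_trend = {"nsAT": trend_nsat, "SST": trend_sst, "SLM": -0.0005,
                      "nsWS": 0.0, "prec": 0.0}
        scen_scale = {"nsAT": 1.0, "SST": 0.8, "SLM": -0.05, "nsWS": 0.05, "prec": 2.0}
        for cov in COVARIATES:
            noise = ar1(T)
            hist = base[cov] + hist_trend[cov] * (yrs - 1950) + noise
            v1 = hist + scen_scale[cov] * anom1
            v5 = hist + scen_scale[cov] * anom5
            for iy, y in enumerate(yrs):
                if y <= 2016:
                    hv = hist[iy] if y <= 2014 else 0.5 * (v1[iy] + v5[iy])
                    records.append(("hindcast", f"colony_{n}", int(y), cov, hv))
                if y >= 2015:
                    records.append(("SSP1", f"colony_{n}", int(y), cov, v1[iy]))
                    records.append(("SSP5", f"colony_{n}", int(y), cov, v5[iy]))
    tab = pd.DataFrame(records, columns=["scenario", "colony", "year", "covariate", "value"])
    return ClimateSeries(tab)


def block_missing_mask(n_years: int, observed_frac: float, rng,
                       mean_run: float = 5.0) -> np.ndarray:
    """Markov on/off censusing: True where a census was taken.

    Run lengths average ``mean_run`` years; the stationary observed
    fraction matches ``observed_frac``.  The final year is always
    observed (modern censuses exist for every colony).
    """
    if observed_frac >= 1.0:
        return np.ones(n_years, dtype=bool)
    p_stay_obs = 1.0 - 1.0 / mean_run
    # stationary fraction f = q_mo/(q_om + q_mo); solve for missing->obs rate
    p_gain = (1.0 - p_stay_obs) * observed_frac / max(1.0 - observed_frac, 1e-9)
    mask = np.empty(n_years, dtype=bool)
    mask[0] = rng.random() < observed_frac
    for t in range(1, n_years):
        p = p_stay_obs if mask[t - 1] else p_gain
        mask[t] = rng.random() < p
    mask[-1] = True
    return mask


def simulate_observations(latent: np.ndarray, bmat: np.ndarray, years, colonies,
                          params: DemographicParams, seed: int,
                          census_frac: float = 0.4, fecundity_frac: float = 0.4,
                          nests_range=(30, 300)):
    """Census counts and fecundity records from a latent trajectory.

    Census: ``round(exp(Normal(log P, sigma_obs)))`` at block-missing
    colony-years.  Fecundity: ``chicks ~ Binomial(nests, b)`` at a
    sparse subset of colony-years, emulating intermittent colony
    monitoring.
    """
    rng = np.random.default_rng(seed)
    years = np.asarray(years)
    n_years, n_col = latent.shape
    census_rows, fec_rows = [], []
    for n, colony in enumerate(colonies):
        mask = block_missing_mask(n_years, census_frac, rng)
        for iy in np.flatnonzero(mask):
            p = latent[iy, n]
            if params.sigma_obs > 0:
                count = int(round(float(np.exp(rng.normal(np.log(max(p, 1e-9)),
                                                          params.sigma_obs)))))
            else:
                count = int(round(p))
            census_rows.append((colony, int(years[iy]), max(count, 0)))
        for iy in range(bmat.shape[0]):
            if rng.random() < fecundity_frac:
                nests = int(rng.integers(nests_range[0], nests_range[1] + 1))
                chicks = int(rng.binomial(nests, bmat[iy, n]))
                fec_rows.append((colony, int(years[iy]), nests, chicks))
    census = pd.DataFrame(census_rows, columns=["colony_id", "year", "aos_count"])
    fecundity = pd.DataFrame(fec_rows, columns=["colony_id", "year", "nests", "chicks"])
    return census, fecundity


def generate_study(seed: int = 1, n_colonies: int = 6, fit_years=(1957, 2016),
                   params: DemographicParams | None = None,
                   spec: ModelSpec = DEFAULT_TRUE_SPEC,
                   census_frac: float = 0.4, fecundity_frac: float = 0.4,
                   init_frac: float = 0.15) -> SyntheticStudy:
    """One complete reproducible synthetic study.

    Climate is generated for 1900–2100, standardized over the 1900–2016
    hindcast; the latent metapopulation runs over ``fit_years`` starting
    from ``init_frac`` of each colony's binding carrying capacity, and
    census/fecundity observations are sampled from it.  HPAI statuses
    default to: northernmost colony unaffected, second-northernmost
    unknown, all others affected.
    """
    if params is None:
        params = default_true_params(n_colonies)
    if params.n_colonies != n_colonies:
        raise ValueError("params.K must have one entry per colony")
    rng = np.random.default_rng(seed)

    climate_raw = generate_climate(n_colonies=n_colonies, seed=seed)
    climate = standardize(climate_raw, window=(1900, 2016))
    colonies = climate.colonies()
    y0, y1 = fit_years
    years = np.arange(y0, y1 + 1)
    T = years.size - 1
    X = climate.to_array("hindcast", colonies, years[:-1])

    # initial sizes: a fraction of the binding capacity in the first year
    from scipy.special import expit, logit as _logit
    eta0 = expit(params.beta0 + sum(
        params.beta_lin.get(c, 0.0) * X[0, :, i] for i, c in enumerate(COVARIATES))
        - sum(params.beta_quad.get(c, 0.0) * X[0, :, i] ** 2
              for i, c in enumerate(COVARIATES)))
    C0 = (params.alpha_const - _logit(params.re)) / eta0
    P0 = init_frac * np.minimum(params.K, C0)

    eps_true = rng.normal(0.0, params.sigma_b, size=T)
    P, J_final, bmat, _ = pk.simulate_trajectory(params, spec, X, eps_true, P0)

    census, fecundity = simulate_observations(
        P, bmat, years, colonies, params, seed=int(rng.integers(2**31 - 1)),
        census_frac=census_frac, fecundity_frac=fecundity_frac)

    hpai = {c: "affected" for c in colonies}
    hpai[colonies[-1]] = "unaffected"
    if n_colonies >= 2:
        hpai[colonies[-2]] = "unknown"

    latent = pd.DataFrame(
        [(c, int(y), float(P[iy, n])) for n, c in enumerate(colonies)
         for iy, y in enumerate(years)],
        columns=["colony", "year", "P"])

    lats = np.linspace(48.0, 71.0, n_colonies)
    return SyntheticStudy(params_true=params, spec_true=spec, climate=climate,
                          colonies=colonies, years=years, latent=latent,
                          eps_true=eps_true, census=census, fecundity=fecundity,
                          hpai_status=hpai, seed=seed, latitudes=lats,
                          J_final=J_final, bmat=bmat)
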