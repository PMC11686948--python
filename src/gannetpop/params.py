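"""Parameter and state containers for the metapopulation model.

Abundances are measured in AOS (Apparently Occupied Sites, ~ breeding
pairs) throughout; demographic rates are probabilities per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical covariate order used everywhere (indices 1..5 in model ids).
COVARIATES: tuple[str, ...] = ("SST", "SLM", "nsAT", "nsWS", "prec")

#: Year of the high-pathogenicity avian influenza adult-survival shock.
HPAI_YEAR: int = 2022

#: Adult survival measured at the one colony where the 2022 HPAI impact
#: was quantified; applied to all known-affected colonies.
HPAI_SURVIVAL_AFFECTED: float = 0.455

#: Upper bound of adult survival (also the prior upper bound for
#: unknown-status colonies in 2022).
MAX_ADULT_SURVIVAL: float = 0.94

HPAI_STATUSES: tuple[str, ...] = ("affected", "unaffected", "unknown")


@dataclass(frozen=True)
class DemographicParams:
    """All process-model parameters.

    Covariate coefficient dicts are keyed by covariate name; quadratic
    magnitudes are stored as non-negative numbers and applied with a
    negative sign (downward parabola) at evaluation time.

    Attributes
    ----------
    alpha0 : float
        Fecundity intercept on the logit scale.
    alpha_lin, alpha_quad : dict[str, float]
        Linear coefficients / quadratic magnitudes of the fecundity
        predictor, per covariate.
    beta0 : float
        Recruitment density-dependence intercept (logit scale).
    beta_lin, beta_quad : dict[str, float]
        Coefficients of the marine density-dependence predictor.
    sigma_b : float
        SD of the shared annual fecundity noise eps_t (logit scale).
    phi_ad, phi_juv : float
        Adult / pre-breeder annual survival probabilities.
    a_first : int
        Age (years) of the first breeding attempt; pre-breeders are
        tracked in ``a_first`` age classes.
    re : float
        Baseline recruitment rate at equilibrium; carrying capacity is
        the colony size at which recruitment falls to ``re``.
    alpha_const : float
        Recruitment steepness constant (dimensionless); large values
        make recruitment ~1 when density effects vanish.
    K : ndarray
        Terrestrial carrying capacity per colony, AOS.
    sigma_obs : float
        Census observation noise SD on the log scale.
    rho : float
        Philopatry factor: a recruiting pre-breeder weighs its natal
        colony as ``rho * P_natal`` against ``P_m`` elsewhere.
    chick_pair_ratio : float
        Conversion from chicks to potential future AOS (two birds per
        site), default 0.5.
    """

    alpha0: float = 0.0
    alpha_lin: dict = field(default_factory=dict)
    alpha_quad: dict = field(default_factory=dict)
    beta0: float = -6.0
    beta_lin: dict = field(default_factory=dict)
    beta_quad: dict = field(default_factory=dict)
    sigma_b: float = 0.3
    phi_ad: float = MAX_ADULT_SURVIVAL
    phi_juv: float = 0.8
    a_first: int = 5
    re: float = 0.3
    alpha_const: float = 100.0
    K: np.ndarray = field(default_factory=lambda: np.array([10_000.0]))
    sigma_obs: float = 0.1
    rho: float = 3.0
    chick_pair_ratio: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float))
        for name, val, lo, hi in (
            ("phi_ad", self.phi_ad, 0.0, 1.0),
            ("phi_juv", self.phi_juv, 0.0, 1.0),
            ("re", self.re, 0.0, 1.0),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if not 0.0 < self.re < 1.0:
            raise ValueError(f"re={self.re} must lie strictly in (0, 1)")
        if self.alpha_const <= 0:
            raise ValueError("alpha_const must be positive")
        if np.any(self.K <= 0):
            raise ValueError("terrestrial carrying capacities K must be positive")
        if self.a_first < 1:
            raise ValueError("a_first must be >= 1")
        for d in (self.alpha_quad, self.beta_quad):
            for cov, mag in d.items():
                if mag < 0:
                    raise ValueError(
                        f"quadratic magnitude for {cov} must be >= 0 "
                        "(the negative sign is applied at evaluation)"
                    )
        unknown = (
            set(self.alpha_lin) | set(self.alpha_quad) | set(self.beta_lin) | set(self.beta_quad)
        ) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariate names: {sorted(unknown)}")

    @property
    def n_colonies(self) -> int:
        return self.K.shape[0]

    def with_(self, **kw) -> "DemographicParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass
class ColonyState:
    """Metapopulation state in a given year.

    ``P[n]`` are breeders (AOS) per colony; ``J[n, a]`` are pre-breeders
    of age class ``a+1`` (a = 0..a_first-1) indexed by natal colony.
    """

    P: np.ndarray
    J: np.ndarray
    year: int

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.P.ndim != 1 or self.J.ndim != 2 or self.J.shape[0] != self.P.shape[0]:
            raise ValueError("P must be (n,) and J (n, a_first)")
        if np.any(self.P < 0) or np.any(self.J < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def n_colonies(self) -> int:
        return self.P.shape[0]

    def copy(self) -> "ColonyState":
        return ColonyState(self.P.copy(), self.J.copy(), self.year)


def equilibrium_prebreeders(P, b, params: DemographicParams) -> np.ndarray:
    """Quasi-equilibrium pre-breeder pool used to initialize simulations.

    Assumes the pipeline of past cohorts was produced at today's colony
    size and fecundity: ``J[:, a] = cpr * b * P * phi_juv**(a+1)`` (the
    first factor of phi_juv is the cohort's first-year survival).
    """
    P = np.asarray(P, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), P.shape)
    ages = np.arange(1, params.a_first + 1)
    return params.chick_pair_ratio * b[:, None] * P[:, None] * params.phi_juv ** ages[None, :]
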