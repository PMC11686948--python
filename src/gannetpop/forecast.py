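"""Scenario forecasting from posterior draws.

Each retained posterior draw is pushed forward from its own fitted 2016
state under the SSP1 and SSP5 covariate series, with the 2022 HPAI
adult-survival shock applied (0.455 at affected colonies, a
Uniform(0.455, 0.94) draw where status is unknown).  The same per-draw
annual-noise and HPAI draws are reused across the two scenarios, so
scenario contrasts reflect climate signal rather than Monte-Carlo noise.

Colony-level climate sensitivity is the percent difference in median
posterior colony size between scenarios, 100·(SSP5 − SSP1)/SSP1:
negative values mean the colony is smaller (disadvantaged) under the
high-emission future.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from . import _engine as eng
from . import _pack as pk
from .inference import MCMCResult
from .params import HPAI_YEAR, DemographicParams

SCENARIOS = ("SSP1", "SSP5")
REFERENCE_YEARS = (2030, 2065, 2100)

TRAJECTORY_CLASSES = ("plateau_same", "diverge_decline", "increase_unbounded",
                      "decline_both")


@dataclass(frozen=True)
class ClassifyThresholds:
    """Rule thresholds for the four forecast-trajectory patterns."""

    same_frac: float = 0.10       # end-horizon scenario difference for "same"
    plateau_tol: float = 0.05     # |relative change| over the final window
    window: int = 20              # years of the late-horizon slope window
    peak_drop: float = 0.90       # SSP5 end below this fraction of its peak
    crash_frac: float = 0.50      # end below this fraction of the early median
    early_year: int = 2030


@dataclass
class ForecastResult:
    """Posterior forecast summaries for both scenarios."""

    colonies: list
    years: np.ndarray                       # state years, fit-end..2100
    P_median: dict = field(default_factory=dict)   # scenario -> (T+1, N)
    P_lo: dict = field(default_factory=dict)
    P_hi: dict = field(default_factory=dict)
    C_median: dict = field(default_factory=dict)   # scenario -> (T, N)
    dominance: dict = field(default_factory=dict)  # scenario -> (T, N) median C-K
    total_median: dict = field(default_factory=dict)
    total_lo: dict = field(default_factory=dict)
    total_hi: dict = field(default_factory=dict)
    total_sum_of_medians: dict = field(default_factory=dict)

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise ValueError(f"year {year} outside the forecast horizon")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scen in SCENARIOS:
            for n, colony in enumerate(self.colonies):
                for iy, y in enumerate(self.years):
                    dom = self.dominance[scen][iy - 1, n] if iy > 0 else np.nan
                    rows.append((scen, colony, int(y),
                                 self.P_median[scen][iy, n],
                                 self.P_lo[scen][iy, n], self.P_hi[scen][iy, n],
                                 self.C_median[scen][iy - 1, n] if iy > 0 else np.nan,
                                 "terrestrial" if not np.isfinite(dom) or dom >= 0
                                 else "marine"))
        return pd.DataFrame(rows, columns=["scenario", "colony", "year", "median",
                                           "lo95", "hi95", "C_median", "regulation"])


def forecast(result: MCMCResult, climate, hpai_statuses, end_year: int = 2100,
             seed: int = 0, n_draws: int = 200) -> ForecastResult:
    """Forward-simulate posterior draws under both scenarios.

    ``climate`` must be the standardized series whose constants were used
    for fitting, with SSP1/SSP5 rows covering the forecast years.  The
    horizon starts at the final fitting year.
    """
    data = result.data
    colonies = data.colonies
    N = len(colonies)
    y_end = int(data.years[-1])
    years_f = np.arange(y_end, end_year + 1)
    T_f = years_f.size - 1
    if T_f < 1:
        raise ValueError("forecast horizon is empty")
    X_scen = {}
    for scen in SCENARIOS:
        X_scen[scen] = climate.to_array(scen, colonies, years_f[:-1])

    hpai_t = HPAI_YEAR - y_end if y_end <= HPAI_YEAR <= years_f[-2] else -1
    code, slot, n_unknown = pk.hpai_arrays(hpai_statuses, N)

    flat = result.flat()
    sel = np.linspace(0, flat.shape[0] - 1, min(n_draws, flat.shape[0])).astype(int)
    rng = np.random.default_rng(seed)

    fixed = pk.fixed_vector(result.template)
    fc, fq, rc, rq = pk.spec_arrays(result.spec)
    layout_fit = result.layout
    if data.hpai_statuses is not None and data.hpai_t >= 0:
        code_fit, slot_fit, _ = pk.hpai_arrays(data.hpai_statuses, N)
    else:
        code_fit = np.zeros(N, dtype=np.int64)
        slot_fit = np.full(N, -1, dtype=np.int64)
    layout_f = pk.build_layout(N, T_f, result.spec, result.template.a_first,
                               hpai_t=hpai_t, n_hpai=n_unknown)

    nD = sel.size
    P_draw = {s: np.empty((nD, T_f + 1, N)) for s in SCENARIOS}
    C_draw = {s: np.empty((nD, T_f, N)) for s in SCENARIOS}
    K_draw = np.empty((nD, N))
    logit_re = logit(result.template.re)
    alpha_c = result.template.alpha_const

    for k, idx in enumerate(sel):
        theta = flat[idx]
        # fitted end state for this draw
        P_hind, J_end, _, _ = eng.simulate(theta, layout_fit, fixed, data.X,
                                           fc, fq, rc, rq, code_fit, slot_fit,
                                           np.zeros(1), np.zeros((1, 1)), 0)
        P0 = P_hind[-1]
        sigma_b = theta[layout_fit[eng.L_OFF_SIGB]]
        eps_f = rng.normal(0.0, sigma_b, size=T_f)
        phi_unknown = rng.uniform(0.455, 0.94, size=n_unknown)
        K_draw[k] = np.exp(theta[layout_fit[eng.L_OFF_LOGK]:
                                 layout_fit[eng.L_OFF_LOGK] + N])
        theta_f = np.zeros(pk.theta_size(layout_f))
        # parameter block layout is identical between fit and forecast
        theta_f[:layout_f[eng.L_OFF_HPAI]] = theta[:layout_fit[eng.L_OFF_HPAI]]
        theta_f[layout_f[eng.L_OFF_HPAI]:layout_f[eng.L_OFF_HPAI] + n_unknown] = phi_unknown
        theta_f[layout_f[eng.L_OFF_LOGK]:layout_f[eng.L_OFF_LOGK] + N] = (
            theta[layout_fit[eng.L_OFF_LOGK]:layout_fit[eng.L_OFF_LOGK] + N])
        theta_f[layout_f[eng.L_OFF_EPS]:layout_f[eng.L_OFF_EPS] + T_f] = eps_f
        for scen in SCENARIOS:
            P_f, _, _, etamat = eng.simulate(theta_f, layout_f, fixed,
                                             X_scen[scen], fc, fq, rc, rq,
                                             code, slot, P0, J_end, 1)
            P_draw[scen][k] = P_f
            C_draw[scen][k] = (alpha_c - logit_re) / etamat

    res = ForecastResult(colonies=colonies, years=years_f)
    for scen in SCENARIOS:
        res.P_median[scen] = np.median(P_draw[scen], axis=0)
        res.P_lo[scen] = np.percentile(P_draw[scen], 2.5, axis=0)
        res.P_hi[scen] = np.percentile(P_draw[scen], 97.5, axis=0)
        res.C_median[scen] = np.median(C_draw[scen], axis=0)
        res.dominance[scen] = np.median(C_draw[scen] - K_draw[:, None, :], axis=0)
        totals = P_draw[scen].sum(axis=2)          # (nD, T+1)
        res.total_median[scen] = np.median(totals, axis=0)
        res.total_lo[scen] = np.percentile(totals, 2.5, axis=0)
        res.total_hi[scen] = np.percentile(totals, 97.5, axis=0)
        res.total_sum_of_medians[scen] = res.P_median[scen].sum(axis=1)
    return res


def sensitivity(result: ForecastResult, year: int) -> pd.DataFrame:
    """Percent difference in median posterior colony size, SSP5 vs SSP1.

    ``100 * (median_SSP5 - median_SSP1) / median_SSP1`` per colony;
    undefined (NaN) where the SSP1 median is zero.
    """
    iy = result.year_index(year)
    m1 = result.P_median["SSP1"][iy]
    m5 = result.P_median["SSP5"][iy]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(m1 > 0, 100.0 * (m5 - m1) / m1, np.nan)
    return pd.DataFrame({"colony": result.colonies, "year": year,
                         "sensitivity_pct": pct})


def _rel_change(series: np.ndarray, window: int) -> float:
    """Relative change over the final ``window`` entries."""
    w = min(window, len(series) - 1)
    ref = series[-1 - w]
    if ref <= 0:
        return 0.0
    return float(series[-1] / ref - 1.0)


def classify_trajectory(ssp1: np.ndarray, ssp5: np.ndarray, years: np.ndarray,
                        thresholds: ClassifyThresholds = ClassifyThresholds()) -> str:
    """Label a colony's paired forecast with one of four patterns.

    Rules (first match wins): drastic decline under both scenarios;
    scenario-indistinguishable plateau; divergence with SSP5 falling off
    its own peak while SSP1 plateaus; unbounded increase under both.
    A residual fallback assigns the nearest pattern by end-horizon
    comparison.
    """
    th = thresholds
    years = np.asarray(years)
    i_early = int(np.argmin(np.abs(years - th.early_year)))
    s1, s5 = np.asarray(ssp1, dtype=float), np.asarray(ssp5, dtype=float)

    crash1 = s1[-1] < th.crash_frac * max(s1[i_early], 1e-12)
    crash5 = s5[-1] < th.crash_frac * max(s5[i_early], 1e-12)
    if crash1 and crash5:
        return "decline_both"

    sl1 = _rel_change(s1, th.window)
    sl5 = _rel_change(s5, th.window)
    end_diff = abs(s5[-1] - s1[-1]) / max(s1[-1], 1e-12)
    if end_diff < th.same_frac and abs(sl1) < th.plateau_tol and abs(sl5) < th.plateau_tol:
        return "plateau_same"
    if abs(sl1) < th.plateau_tol and s5[-1] < th.peak_drop * s5.max():
        return "diverge_decline"
    if sl1 > th.plateau_tol and sl5 > th.plateau_tol:
        return "increase_unbounded"
    # fallback: nearest pattern
    if end_diff < th.same_frac:
        return "plateau_same"
    return "diverge_decline" if s5[-1] < s1[-1] else "increase_unbounded"


def classify_all(result: ForecastResult,
                 thresholds: ClassifyThresholds = ClassifyThresholds()) -> dict:
    """Trajectory class per colony from the median forecasts."""
    out = {}
    for n, colony in enumerate(result.colonies):
        out[colony] = classify_trajectory(result.P_median["SSP1"][:, n],
                                          result.P_median["SSP5"][:, n],
                                          result.years, thresholds)
    return out
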