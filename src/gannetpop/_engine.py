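"""Numba kernels: trajectory simulation, joint density, and the sampler.

The process model has a single shared process-noise term per year (the
annual fecundity deviation eps_t), so a latent trajectory is a
deterministic function of the parameters, the initial log colony sizes
and the eps series.  The sampler therefore runs adaptive random-walk
Metropolis-within-Gibbs over one flat parameter vector ``theta`` holding,
in order:

====================  ======================================
slot                  content
====================  ======================================
``0``                 alpha0 (fecundity intercept)
``off_flin  + i``     fecundity linear coefficient, term i
``off_fquad + i``     fecundity quadratic magnitude, term i
``off_beta0``         beta0 (recruitment-DD intercept)
``off_rlin  + i``     recruitment linear coefficient, term i
``off_rquad + i``     recruitment quadratic magnitude, term i
``off_sigb``          sigma_b   (annual fecundity noise SD)
``off_sigobs``        sigma_obs (census log-scale noise SD)
``off_hpai  + k``     2022 survival, k-th unknown-status colony
``off_logK  + n``     log terrestrial carrying capacity
``off_logP0 + n``     log initial colony size
``off_eps   + t``     annual fecundity deviation eps_t
====================  ======================================

Quadratic slots exist for every covariate term but are only swept when
the model structure includes the quadratic; unswept slots stay 0.

Because the trajectory is deterministic, a proposal that changes eps_t
leaves years before t untouched; the sampler exploits this by
re-simulating only from the first affected year (``coord_tstart``),
which roughly halves the cost of a full sweep.
"""

import math

import numpy as np
from numba import njit

# layout indices
L_N = 0        # colonies
L_T = 1        # transition years (states run 0..T)
L_A = 2        # pre-breeder age classes (= age of first breeding)
L_NF = 3       # fecundity covariate terms
L_NR = 4       # recruitment covariate terms
L_OFF_FLIN = 5
L_OFF_FQUAD = 6
L_OFF_BETA0 = 7
L_OFF_RLIN = 8
L_OFF_RQUAD = 9
L_OFF_SIGB = 10
L_OFF_SIGOBS = 11
L_OFF_HPAI = 12
L_NHPAI = 13
L_OFF_LOGK = 14
L_OFF_LOGP0 = 15
L_OFF_EPS = 16
L_HPAI_T = 17  # index of the 2022 transition, -1 if outside the window
L_SIZE = 18

# fixed-parameter indices
F_PHI_AD = 0
F_PHI_JUV = 1
F_ALPHA = 2    # recruitment steepness constant
F_LOGIT_RE = 3
F_RHO = 4
F_CPR = 5      # chick -> pair conversion
F_SIZE = 6

# prior hyperparameter indices
P_INT_SD = 0      # intercept prior SD
P_LIN_SD = 1      # linear-coefficient prior SD
P_SDLOGK = 2      # SD of log K around the expert value
P_LOGP0_MEAN = 3
P_LOGP0_SD = 4
P_SIG_SD = 5      # half-normal SD for sigma_b / sigma_obs
P_HPAI_LO = 6
P_HPAI_HI = 7
P_SIZE = 8

# coordinate classes for partial recomputation
TS_PRIOR_ONLY = -2   # sigma_b: likelihood unchanged
TS_OBS_ONLY = -3     # sigma_obs: observation density only

_LOG2PI = math.log(2.0 * math.pi)


@njit(cache=False)
def simulate_span(theta, layout, fixed, X, fec_cov, fec_quad, rec_cov, rec_quad,
                  hpai_code, hpai_slot, t0, init_from_theta, P, J, bmat, etamat):
    """Fill the trajectory arrays in place from transition ``t0`` onward.

    ``P`` is (T+1, N), ``J`` is (T+1, N, A) (pre-breeder state at the
    START of each year), ``bmat``/``etamat`` are (T, N).  The state at
    ``t0`` must already be present in ``P[t0]``/``J[t0]`` unless
    ``t0 == 0 and init_from_theta == 1``, in which case P[0] comes from
    the theta log-P0 slots and J[0] is set to the quasi-equilibrium
    pipeline of the year-0 fecundity.
    """
    N = layout[L_N]
    T = layout[L_T]
    A = layout[L_A]
    nf = layout[L_NF]
    nr = layout[L_NR]
    phi_ad = fixed[F_PHI_AD]
    phi_juv = fixed[F_PHI_JUV]
    alpha_c = fixed[F_ALPHA]
    logit_re = fixed[F_LOGIT_RE]
    rho = fixed[F_RHO]
    cpr = fixed[F_CPR]
    hpai_t = layout[L_HPAI_T]

    off_flin = layout[L_OFF_FLIN]
    off_fquad = layout[L_OFF_FQUAD]
    off_rlin = layout[L_OFF_RLIN]
    off_rquad = layout[L_OFF_RQUAD]
    off_eps = layout[L_OFF_EPS]
    off_hpai = layout[L_OFF_HPAI]
    alpha0 = theta[0]
    beta0 = theta[layout[L_OFF_BETA0]]

    nu = np.empty(N)
    for n in range(N):
        nu[n] = (alpha_c - logit_re) / math.exp(theta[layout[L_OFF_LOGK] + n])

    if t0 == 0 and init_from_theta == 1:
        for n in range(N):
            P[0, n] = math.exp(theta[layout[L_OFF_LOGP0] + n])

    W = np.empty((N, N))
    arrivals = np.empty(N)
    Q = np.empty(N)
    rvec = np.empty(N)
    failed = np.empty(N)

    for t in range(t0, T):
        eps = theta[off_eps + t]
        for n in range(N):
            # fecundity predictor
            lp = alpha0 + eps
            for i in range(nf):
                x = X[t, n, fec_cov[i]]
                lp += theta[off_flin + i] * x
                if fec_quad[i] == 1:
                    lp -= theta[off_fquad + i] * x * x
            bmat[t, n] = 1.0 / (1.0 + math.exp(-lp))
            # marine density-dependence predictor
            lq = beta0
            for i in range(nr):
                x = X[t, n, rec_cov[i]]
                lq += theta[off_rlin + i] * x
                if rec_quad[i] == 1:
                    lq -= theta[off_rquad + i] * x * x
            etamat[t, n] = 1.0 / (1.0 + math.exp(-lq))

        if t == 0 and init_from_theta == 1:
            # quasi-equilibrium pre-breeder pipeline from today's output
            for n in range(N):
                base = cpr * bmat[0, n] * P[0, n]
                f = phi_juv
                for a in range(A):
                    J[0, n, a] = base * f
                    f *= phi_juv

        # conspecific-attraction movement weights from current sizes
        for n in range(N):
            rowsum = 0.0
            for m in range(N):
                w = rho * P[t, n] if m == n else P[t, m]
                W[n, m] = w
                rowsum += w
            if rowsum > 0.0:
                for m in range(N):
                    W[n, m] /= rowsum
            else:
                for m in range(N):
                    W[n, m] = 1.0 if m == n else 0.0

        # recruitment-age pool, redistribution, recruitment at the target
        for n in range(N):
            arrivals[n] = 0.0
            Q[n] = phi_juv * J[t, n, A - 1]
        for n in range(N):
            for m in range(N):
                arrivals[m] += Q[n] * W[n, m]
        for m in range(N):
            dd = nu[m]
            if etamat[t, m] > dd:
                dd = etamat[t, m]
            rvec[m] = 1.0 / (1.0 + math.exp(-(alpha_c - dd * P[t, m])))
        for n in range(N):
            s = 0.0
            for m in range(N):
                s += W[n, m] * (1.0 - rvec[m])
            failed[n] = Q[n] * s
        # adult survival (HPAI shock year overrides)
        for n in range(N):
            if t == hpai_t:
                code = hpai_code[n]
                if code == 0:
                    phi = 0.455
                elif code == 1:
                    phi = phi_ad
                else:
                    phi = theta[off_hpai + hpai_slot[n]]
            else:
                phi = phi_ad
            P[t + 1, n] = phi * P[t, n] + arrivals[n] * rvec[n]
        # age the pre-breeder pipeline into next year's state; the new
        # cohort takes its first-year survival at creation, and failed
        # recruits (already survived this year via Q) retry next year
        for n in range(N):
            for a in range(A - 1, 0, -1):
                J[t + 1, n, a] = phi_juv * J[t, n, a - 1]
            J[t + 1, n, 0] = phi_juv * cpr * bmat[t, n] * P[t, n]
            J[t + 1, n, A - 1] += failed[n]


@njit(cache=False)
def simulate(theta, layout, fixed, X, fec_cov, fec_quad, rec_cov, rec_quad,
             hpai_code, hpai_slot, P0_in, J0_in, use_state):
    """Full deterministic trajectory; returns (P, J_final, bmat, etamat).

    When ``use_state`` is 0 the initial state comes from theta; otherwise
    from ``P0_in`` (N,) and ``J0_in`` (N, A).
    """
    N = layout[L_N]
    T = layout[L_T]
    A = layout[L_A]
    P = np.empty((T + 1, N))
    J = np.zeros((T + 1, N, A))
    bmat = np.empty((T, N))
    etamat = np.empty((T, N))
    if use_state == 1:
        for n in range(N):
            P[0, n] = P0_in[n]
            for a in range(A):
                J[0, n, a] = J0_in[n, a]
        simulate_span(theta, layout, fixed, X, fec_cov, fec_quad, rec_cov,
                      rec_quad, hpai_code, hpai_slot, 0, 0, P, J, bmat, etamat)
    else:
        simulate_span(theta, layout, fixed, X, fec_cov, fec_quad, rec_cov,
                      rec_quad, hpai_code, hpai_slot, 0, 1, P, J, bmat, etamat)
    return P, J[T], bmat, etamat


@njit(cache=False)
def obs_loglik(P, bmat, sigo, cobs_t, cobs_n, cobs_logy, fobs_t, fobs_n,
               fobs_nests, fobs_chicks, fobs_lgconst):
    """Observation log-likelihood from one trajectory."""
    ll = 0.0
    for k in range(cobs_t.shape[0]):
        p = P[cobs_t[k], cobs_n[k]]
        if p <= 1e-300:
            return -np.inf
        z = (cobs_logy[k] - math.log(p)) / sigo
        ll += -0.5 * z * z - math.log(sigo) - 0.5 * _LOG2PI
    for k in range(fobs_t.shape[0]):
        b = bmat[fobs_t[k], fobs_n[k]]
        if b <= 0.0 or b >= 1.0:
            return -np.inf
        ll += (fobs_chicks[k] * math.log(b)
               + (fobs_nests[k] - fobs_chicks[k]) * math.log(1.0 - b)
               + fobs_lgconst[k])
    return ll


@njit(cache=False)
def obs_loglik_mixed(P_cur, b_cur, P_prop, b_prop, t0, sigo,
                     cobs_t, cobs_n, cobs_logy, fobs_t, fobs_n,
                     fobs_nests, fobs_chicks, fobs_lgconst):
    """Observation log-likelihood when only years >= t0 were re-simulated.

    Terms from state/transition index t0 onward read the proposal arrays
    (P_prop[t0] either equals the current state or was refreshed from
    theta when t0 = 0); earlier terms read the current arrays.
    """
    ll = 0.0
    for k in range(cobs_t.shape[0]):
        t = cobs_t[k]
        p = P_prop[t, cobs_n[k]] if t >= t0 else P_cur[t, cobs_n[k]]
        if p <= 1e-300:
            return -np.inf
        z = (cobs_logy[k] - math.log(p)) / sigo
        ll += -0.5 * z * z - math.log(sigo) - 0.5 * _LOG2PI
    for k in range(fobs_t.shape[0]):
        t = fobs_t[k]
        b = b_prop[t, fobs_n[k]] if t >= t0 else b_cur[t, fobs_n[k]]
        if b <= 0.0 or b >= 1.0:
            return -np.inf
        ll += (fobs_chicks[k] * math.log(b)
               + (fobs_nests[k] - fobs_chicks[k]) * math.log(1.0 - b)
               + fobs_lgconst[k])
    return ll


@njit(cache=False)
def log_likelihood(theta, layout, fixed, X, fec_cov, fec_quad, rec_cov, rec_quad,
                   hpai_code, hpai_slot,
                   cobs_t, cobs_n, cobs_logy, fobs_t, fobs_n, fobs_nests,
                   fobs_chicks, fobs_lgconst):
    """Observation log-likelihood: log-normal census + binomial fecundity."""
    dummyP = np.zeros(1)
    dummyJ = np.zeros((1, 1))
    P, J, bmat, etamat = simulate(theta, layout, fixed, X, fec_cov, fec_quad,
                                  rec_cov, rec_quad, hpai_code, hpai_slot,
                                  dummyP, dummyJ, 0)
    return obs_loglik(P, bmat, theta[layout[L_OFF_SIGOBS]], cobs_t, cobs_n,
                      cobs_logy, fobs_t, fobs_n, fobs_nests, fobs_chicks,
                      fobs_lgconst)


@njit(cache=False)
def log_prior(theta, layout, fixed, hyper, fec_quad, rec_quad, logK_expert):
    """Sum of prior log-densities; -inf outside the support."""
    lp = 0.0
    nf = layout[L_NF]
    nr = layout[L_NR]
    # intercepts
    c_int = -math.log(hyper[P_INT_SD]) - 0.5 * _LOG2PI
    v = theta[0]
    lp += c_int - 0.5 * (v / hyper[P_INT_SD]) ** 2
    v = theta[layout[L_OFF_BETA0]]
    lp += c_int - 0.5 * (v / hyper[P_INT_SD]) ** 2
    c_lin = -math.log(hyper[P_LIN_SD]) - 0.5 * _LOG2PI
    # fecundity coefficients
    for i in range(nf):
        v = theta[layout[L_OFF_FLIN] + i]
        if fec_quad[i] == 1:
            # parabola: Gamma(1,1) on the positive linear coefficient
            if v < 0.0:
                return -np.inf
            lp += -v
            q = theta[layout[L_OFF_FQUAD] + i]
            if q < 0.0:
                return -np.inf
            lp += -q
        else:
            lp += c_lin - 0.5 * (v / hyper[P_LIN_SD]) ** 2
    # recruitment coefficients
    for i in range(nr):
        v = theta[layout[L_OFF_RLIN] + i]
        if rec_quad[i] == 1:
            if v < 0.0:
                return -np.inf
            lp += -v
            q = theta[layout[L_OFF_RQUAD] + i]
            if q < 0.0:
                return -np.inf
            lp += -q
        else:
            lp += c_lin - 0.5 * (v / hyper[P_LIN_SD]) ** 2
    # noise scales: half-normal
    sigb = theta[layout[L_OFF_SIGB]]
    sigo = theta[layout[L_OFF_SIGOBS]]
    if sigb <= 0.0 or sigo <= 0.0:
        return -np.inf
    c_half = math.log(2.0) - math.log(hyper[P_SIG_SD]) - 0.5 * _LOG2PI
    lp += c_half - 0.5 * (sigb / hyper[P_SIG_SD]) ** 2
    lp += c_half - 0.5 * (sigo / hyper[P_SIG_SD]) ** 2
    # unknown-status HPAI survival: uniform
    for k in range(layout[L_NHPAI]):
        v = theta[layout[L_OFF_HPAI] + k]
        if v < hyper[P_HPAI_LO] or v > hyper[P_HPAI_HI]:
            return -np.inf
        lp += -math.log(hyper[P_HPAI_HI] - hyper[P_HPAI_LO])
    # log K around expert elicitation
    c_k = -math.log(hyper[P_SDLOGK]) - 0.5 * _LOG2PI
    for n in range(layout[L_N]):
        v = theta[layout[L_OFF_LOGK] + n] - logK_expert[n]
        lp += c_k - 0.5 * (v / hyper[P_SDLOGK]) ** 2
    # initial log sizes (vague)
    c_p0 = -math.log(hyper[P_LOGP0_SD]) - 0.5 * _LOG2PI
    for n in range(layout[L_N]):
        v = theta[layout[L_OFF_LOGP0] + n] - hyper[P_LOGP0_MEAN]
        lp += c_p0 - 0.5 * (v / hyper[P_LOGP0_SD]) ** 2
    # annual fecundity deviations, hierarchical on sigma_b
    T = layout[L_T]
    for t in range(T):
        e = theta[layout[L_OFF_EPS] + t]
        lp += -0.5 * (e / sigb) ** 2
    lp += -T * (math.log(sigb) + 0.5 * _LOG2PI)
    return lp


@njit(cache=False)
def run_chain(theta0, sampled, coord_tstart, scales0, n_iter, n_burn, thin, seed,
              layout, fixed, hyper, X, fec_cov, fec_quad, rec_cov, rec_quad,
              hpai_code, hpai_slot, logK_expert,
              cobs_t, cobs_n, cobs_logy, fobs_t, fobs_n, fobs_nests,
              fobs_chicks, fobs_lgconst):
    """One adaptive Metropolis-within-Gibbs chain.

    Per-coordinate Gaussian random-walk proposals; proposal scales adapt
    toward 44% acceptance in windows of 50 sweeps during burn-in and are
    frozen afterwards.  ``coord_tstart`` gives, per coordinate, the first
    transition year whose state it can alter (or the TS_* sentinels for
    prior-only / observation-only coordinates).  Returns (draws,
    loglik_per_draw, final_scales, acceptance_rates).
    """
    np.random.seed(seed)
    N = layout[L_N]
    T = layout[L_T]
    A = layout[L_A]
    theta = theta0.copy()
    scales = scales0.copy()
    nS = sampled.shape[0]
    off_sigobs = layout[L_OFF_SIGOBS]

    P_cur = np.empty((T + 1, N))
    J_cur = np.zeros((T + 1, N, A))
    b_cur = np.empty((T, N))
    e_cur = np.empty((T, N))
    P_prop = np.empty((T + 1, N))
    J_prop = np.zeros((T + 1, N, A))
    b_prop = np.empty((T, N))
    e_prop = np.empty((T, N))

    simulate_span(theta, layout, fixed, X, fec_cov, fec_quad, rec_cov, rec_quad,
                  hpai_code, hpai_slot, 0, 1, P_cur, J_cur, b_cur, e_cur)
    lpr = log_prior(theta, layout, fixed, hyper, fec_quad, rec_quad, logK_expert)
    ll = obs_loglik(P_cur, b_cur, theta[off_sigobs], cobs_t, cobs_n, cobs_logy,
                    fobs_t, fobs_n, fobs_nests, fobs_chicks, fobs_lgconst)
    lp = lpr + ll

    n_keep = (n_iter - n_burn) // thin
    draws = np.empty((n_keep, theta.shape[0]))
    lls = np.empty(n_keep)
    acc_win = np.zeros(theta.shape[0])
    acc_tot = np.zeros(theta.shape[0])
    window = 50
    kept = 0

    for it in range(n_iter):
        for jj in range(nS):
            j = sampled[jj]
            ts = coord_tstart[j]
            old = theta[j]
            theta[j] = old + scales[j] * np.random.normal()
            lpr_new = log_prior(theta, layout, fixed, hyper, fec_quad,
                                rec_quad, logK_expert)
            if lpr_new == -np.inf:
                theta[j] = old
                continue
            if ts == TS_PRIOR_ONLY:
                ll_new = ll
            elif ts == TS_OBS_ONLY:
                ll_new = obs_loglik(P_cur, b_cur, theta[off_sigobs], cobs_t,
                                    cobs_n, cobs_logy, fobs_t, fobs_n,
                                    fobs_nests, fobs_chicks, fobs_lgconst)
            else:
                if ts > 0:
                    for n in range(N):
                        P_prop[ts, n] = P_cur[ts, n]
                        for a in range(A):
                            J_prop[ts, n, a] = J_cur[ts, n, a]
                    simulate_span(theta, layout, fixed, X, fec_cov, fec_quad,
                                  rec_cov, rec_quad, hpai_code, hpai_slot,
                                  ts, 0, P_prop, J_prop, b_prop, e_prop)
                else:
                    simulate_span(theta, layout, fixed, X, fec_cov, fec_quad,
                                  rec_cov, rec_quad, hpai_code, hpai_slot,
                                  0, 1, P_prop, J_prop, b_prop, e_prop)
                ll_new = obs_loglik_mixed(P_cur, b_cur, P_prop, b_prop, ts,
                                          theta[off_sigobs], cobs_t, cobs_n,
                                          cobs_logy, fobs_t, fobs_n, fobs_nests,
                                          fobs_chicks, fobs_lgconst)
            lp_new = lpr_new + ll_new
            if lp_new - lp > math.log(np.random.random() + 1e-300):
                lp = lp_new
                ll = ll_new
                acc_win[j] += 1.0
                acc_tot[j] += 1.0
                if ts != TS_PRIOR_ONLY and ts != TS_OBS_ONLY:
                    t0c = ts if ts > 0 else 0
                    for t in range(t0c, T + 1):
                        for n in range(N):
                            P_cur[t, n] = P_prop[t, n]
                            for a in range(A):
                                J_cur[t, n, a] = J_prop[t, n, a]
                    for t in range(t0c, T):
                        for n in range(N):
                            b_cur[t, n] = b_prop[t, n]
                            e_cur[t, n] = e_prop[t, n]
            else:
                theta[j] = old
        if it < n_burn:
            if (it + 1) % window == 0:
                for jj in range(nS):
                    j = sampled[jj]
                    rate = acc_win[j] / window
                    scales[j] *= math.exp(1.2 * (rate - 0.44))
                    if scales[j] < 1e-7:
                        scales[j] = 1e-7
                    elif scales[j] > 50.0:
                        scales[j] = 50.0
                    acc_win[j] = 0.0
        else:
            if (it - n_burn) % thin == thin - 1 and kept < n_keep:
                for q in range(theta.shape[0]):
                    draws[kept, q] = theta[q]
                lls[kept] = ll
                kept += 1
    acc_rate = acc_tot / max(1, n_iter - n_burn)
    return draws, lls, scales, acc_rate
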