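# Methods

## Process model

The metapopulation state in year `t` is the vector of breeder counts
`P_{n,t}` (AOS) plus a pre-breeder pipeline `J_{n,a}`, `a = 1..a_first`,
indexed by natal colony. One annual transition applies, in order:

1. **Fecundity.** `logit b_{n,t} = alpha_0 + Σ_i (alpha_i X_{i,n,t} −
   alphaq_i X_{i,n,t}^2) + eps_t`. Quadratic magnitudes `alphaq_i >= 0`
   carry their negative sign at evaluation, so any climate optimum is a
   downward parabola. `eps_t ~ N(0, sigma_b)` is shared across colonies
   within a year (it is indexed by year only); it is the model's only
   process noise.
2. **Recruitment.** The marine density-dependence coefficient
   `eta_{n,t}` follows the same linear-predictor form (no noise term);
   the terrestrial coefficient is `nu_n = (alpha − logit(r_e))/K_n`.
   Recruitment `r_{n,t} = logit^{-1}(alpha − max(nu_n, eta_{n,t})
   P_{n,t})` uses whichever coefficient is larger, i.e. whichever
   implied capacity (`K_n` terrestrial, `C_{n,t} = (alpha −
   logit(r_e))/eta_{n,t}` marine) is smaller. With the steepness
   constant `alpha = 100`, recruitment is indistinguishable from 1 at
   `P = 0` and equals `r_e` exactly at the binding capacity.
3. **Movement and recruitment of the oldest cohort.** Pre-breeders
   reaching `a_first` (after that year's survival `phi_juv`) are
   redistributed over colonies with conspecific-attraction weights
   `w_{n→m} ∝ P_m`, the natal colony up-weighted by a philopatry factor
   `rho` (`w_{n→n} ∝ rho·P_n`), rows normalized; movement conserves
   individuals. Arrivals recruit with the target colony's `r_{m,t}`;
   failures return to the natal pool and retry annually until death.
4. **Survival and aging.** Adults survive with `phi_ad` (2022: the HPAI
   override). The new cohort `phi_juv · c · b_{n,t} · P_{n,t}` enters
   class 1 — `c = 0.5` converts chicks to potential breeding pairs (two
   birds per site) and the leading `phi_juv` is first-year survival —
   and older classes age with survival `phi_juv`.

All abundances are expected values (non-negative reals); demographic
integer noise is not modelled, consistent with colony sizes spanning
10^2–10^5 AOS. Forward simulations are bit-reproducible given a seed.

### Stage bookkeeping

Every pre-breeder faces annual survival exactly once per year: at
creation (first year), at each aging step, and in the pooled
recruitment-transition year. Consequently all abundances vanish after
one step if both survivals are zero. A cohort therefore experiences
`a_first + 1` survival factors before its first breeding attempt; the
extra factor is the transition year in which it travels and recruits.

### Dynamics near capacity

With `alpha = 100` the recruitment logistic is nearly a threshold at
the binding capacity. Combined with the 5-year recruitment delay this
produces, in deterministic constant-climate runs, a bounded
overcompensation cycle (~±10–20% around `min(C, K)`) rather than a
stable fixed point; the time-average sits at capacity and excursions
above it stay within the recruitment tail. At gentler steepness (e.g.
`alpha = 20`) the fixed point is stable and trajectories converge
exactly. Immigration through conspecific attraction can also hold a
receiving colony slightly (~1%) above its own capacity at equilibrium.
The tests assert both regimes.

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| `phi_ad` | 0.94 | 1/yr | maximum adult survival of the predecessor demographic analysis |
| `phi_juv` | 0.8 | 1/yr | plausible immature survival for a long-lived sulid |
| `a_first` | 5 | yr | age at first breeding attempt in gannets |
| `rho` | 3 | – | natal-colony attraction boost; conspecific attraction with philopatry |
| `r_e` | 0.3 | – | baseline recruitment at equilibrium (not published; config-exposed, shared by `nu`, `C`) |
| `alpha` | 100 | – | recruitment steepness; makes `r(0) ≈ 1` |
| `c` (chick→pair) | 0.5 | – | two birds per breeding site |
| `sigma_b` | 0.3 | logit | moderate interannual fecundity variation |
| `sigma_obs` | 0.1 | log AOS | ~10% multiplicative census error |

Coefficient defaults in the synthetic generator are the posterior
medians of the best-fitting published structure (fecundity intercept
0.969, nsAT linear 1.546, nsAT quadratic 0.848, precipitation 0.139;
recruitment intercept −6.619, SST 0.881), so the synthetic system
reproduces the qualitative regime of the real one: an interior air-
temperature optimum for fecundity (peak 0.84 chicks/nest at the
parabola vertex) and SST-driven marine capacities that bind for large
colonies.

## Covariate construction

Monthly gridded fields are reduced to one number per colony-year by
averaging February–September (the colony-attendance season), weighting
cells by the colony's at-sea density surface, and summing. Surfaces are
kept fixed within 20-year epochs (1900, 1920, …, 2000, 2016); forecast
years use the 2016 surface. Because hindcast fields end in 2014, the
2015–2016 fitting-window values are the mean of the two scenario
fields. Covariates are z-scored with constants pooled over colonies and
years of the fitting window — the regression coefficients are shared
across colonies, so all colonies must sit on one scale — and the same
constants are applied to forecast years (whose z-scores may then leave
the fitting range; that is the signal).

Two deliberate simplifications: (1) density surfaces are weighted
*means* (weights normalized to 1) rather than weighted sums — an
unnormalized sum would scale covariates with colony size and break the
shared z-scored response curves; (2) the surface generator is a
phenomenological exponential kernel over sea cells, range ∝ sqrt(colony
size), with overlapping colonies splitting cells in proportion to their
kernel values as a competitive-exclusion proxy. It reproduces the
mechanistic surfaces' roles (land avoidance, size-dependent range,
neighbour competition) but none of their within-colony density-dependence
detail; covariate values extracted through it are smooth functions of
colony geometry, not predictions of real foraging distributions.

## Synthetic studies

`generate_study` builds: (a) colony-level climate with a latitude-
dependent baseline (~10 °C of nsAT across six colonies, 48–71° N), a
linear historical warming trend, AR(1) interannual noise (lag-1
correlation 0.5), and post-2014 scenario paths — SSP1 adds ~1 °C by
2100 and levels off, SSP5 adds ~4 °C accelerating, with shared noise
innovations so scenario contrasts are pure signal; (b) a latent
trajectory from the process model; (c) censuses at ~40% of colony-years
in multi-year blocks (Markov on/off censusing, mean run 5 years, final
year always observed) with log-normal error rounded to integers; and
(d) binomial fecundity records at ~40% of colony-years with 30–300
nests — matching the sparse, intermittent structure of real colony
monitoring. Terrestrial capacities span 8,000–250,000 AOS so that the
marine capacity binds for the large colonies and the terrestrial one
for the small.

What passing tests on these data do **not** show: robustness to
observation models other than the generating one (real census error is
not log-normal-iid, real productivity monitoring is not binomial-
at-random), to mis-specified climate responses, or to the spatial
covariance of real CMIP6 fields. They validate the estimation machinery
under the model's own assumptions, not the model against nature.

## Inference

The only process noise is `eps_t`, so a latent trajectory is a
deterministic function of (parameters, initial log sizes, eps series).
The sampler therefore treats the initial log sizes and the eps series
as the latent variables — the actual degrees of freedom — and runs
adaptive random-walk Metropolis-within-Gibbs over every coordinate:
Gaussian proposals per coordinate, scales adapted toward 44% acceptance
in windows of 50 sweeps during burn-in and frozen afterwards. Because a
proposal that changes `eps_t` leaves years before `t` untouched, the
likelihood re-simulates only from the first affected year; `sigma_b`
touches only the prior and `sigma_obs` only the observation density.
Per-colony-year latent summaries come from pushing retained draws
through the deterministic process.

Priors: N(0,1) on linear climate coefficients; Gamma(1,1) on the
magnitudes of sign-constrained parabola pairs (linear +, quadratic −);
N(0,10) on the two intercepts (the published recruitment intercept
median, −6.6, is far outside a unit normal, so intercepts need a wider
scale); Half-Normal(1) on `sigma_b`, `sigma_obs`; log-normal on `K_n`
centred on the expert value with 20% CV; N(log 500, 3) on initial log
sizes; Uniform(0.455, 0.94) on 2022 survival at unknown-status
colonies. Census likelihood uses `log(count)` with zero counts mapped
to `log 0.5`.

Defaults mirror the published protocol (4 chains × 100,000 iterations,
burn-in 15,000, thinning 200); all settings scale down for desk-scale
work, and the simulation studies in the test suite use 4 × 5,000
(recovery) and 4 × 1,500 (selection) — sizes chosen so a full study
runs on one CPU in minutes while still passing coverage checks.
Chains are seeded `seed + chain_index`. Convergence is declared at
Gelman–Rubin R-hat < 1.1 (classic non-split PSRF) on every sampled
coordinate; non-converged fits are reported but excluded from "best
model" selection. DIC focuses the deviance on the observation level
conditional on the latent quantities, `pD = Dbar − D(posterior mean)`,
with `pD` reported as computed even if negative. ΔDIC is defined as
`DIC_null − DIC_model`, so better models have larger ΔDIC.

Initialization is data-informed (fecundity intercept from the pooled
chick rate, initial sizes from first censuses, recruitment intercept
set so the implied marine capacity starts well above the largest
count) with per-chain jitter; this affects burn-in length only, not
the target distribution.

## Forecasting

Each retained draw is re-simulated over the fitting window to obtain
its own end state (breeders and pre-breeder pipeline), then pushed to
2100 under each scenario's covariates, drawing `eps_t` from that draw's
`sigma_b` and applying the 2022 HPAI shock (0.455 affected; regular
survival unaffected; a fresh Uniform(0.455, 0.94) draw where unknown).
The same per-draw noise and HPAI draws are reused across scenarios, so
with identical climate inputs the paired trajectories are identical and
all sensitivities are exactly zero — scenario contrasts are climate
signal, not Monte-Carlo noise.

Sensitivity at a reference year (2030/2065/2100) is
`100·(median_SSP5 − median_SSP1)/median_SSP1` per colony, undefined
(reported missing) when the SSP1 median is zero; the signed SSP1-
denominator form is used so "X% larger under SSP5" reads literally.
Metapopulation trajectories are summarized as the median of per-draw
totals (it respects cross-colony correlation); the sum of colony
medians is also reported since the two differ. Capacity-dominance
series are the per-draw median of `C_{n,t} − K_n` (each draw's own K),
so regime switches occur exactly where the median difference crosses
zero.

Trajectory classification (thresholds config-exposed, first match
wins): *decline-both* if the end-horizon median falls below 50% of the
2030 median under both scenarios; *plateau-same* if the scenarios end
within 10% of each other and both late-horizon slopes (relative change
over the final 20 years) are within ±5%; *diverge-decline* if SSP1
plateaus while the SSP5 end median is below 90% of its own peak;
*increase-unbounded* if both late slopes exceed +5%. A residual
fallback assigns the nearest pattern by end-horizon comparison. The
published shares of these patterns are properties of the real data and
are not reproduced at desk scale; the rules are exercised on
constructed trajectories and on synthetic forecasts.

## Numerical notes

* The trajectory/likelihood kernels and the sampler inner loop are
  numba-jitted; the readable NumPy stepper (`step_metapopulation`) is
  the reference implementation and a test pins the two to 1e-12
  relative agreement.
* Movement weights degenerate gracefully: an all-empty metapopulation
  keeps pools at their natal colonies.
* `max(nu, eta)` ties are labelled terrestrial regulation.
* Proposal-scale bounds [1e-7, 50] guard against adaptation runaway on
  flat directions (e.g. unidentified `K_n` at marine-regulated
  colonies, where the posterior correctly reverts to the prior).
* Likelihood evaluations return −inf for non-positive latent sizes or
  degenerate fecundities; the sampler rejects such proposals.

## Known limitations

* The pre-breeder reconstruction (stage count, `phi_juv`, `rho`, the
  chick→pair factor) stands in for an unpublished predecessor
  formulation; all of it is config-exposed and none of it is informed
  by data here.
* Movement ignores distance: a colony 2,000 km away with the same size
  attracts equally. No colonisation of empty sites.
* `eps_t` shared across colonies means fecundity shocks are perfectly
  spatially correlated; real shocks are regional.
* DIC is the only criterion implemented (matching the study design);
  WAIC/LOO are out of scope.
* The sampler is single-site and will mix slowly on strongly correlated
  posteriors (e.g. `beta_0` vs `K_n` when regulation regime is
  ambiguous); the desk-scale settings were validated by coverage
  simulation, not by asymptotics.
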