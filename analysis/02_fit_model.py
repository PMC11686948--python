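#!/usr/bin/env python
"""Fit the generating model structure to the baseline study by MCMC.

Reads the fixtures written by 01_simulate_study.py, runs the adaptive
Metropolis-within-Gibbs sampler (4 chains x 5,000 iterations at desk
scale), and reports posterior medians and 95% credible intervals next to
the generating values, plus convergence diagnostics and DIC.
"""

import json
import time
from pathlib import Path

import numpy as np

from gannetpop import inference as inf
from gannetpop import io as gio
from gannetpop.modelspec import ModelSpec
from gannetpop.params import DemographicParams

DATA = Path("results/data")
OUT = Path("results/fit")
SEED = 11

TRUTH = {"alpha0": 0.969, "alpha_nsAT": 1.546, "alpha_nsAT_sq": 0.848,
         "alpha_prec": 0.139, "beta0": -6.619, "beta_SST": 0.881,
         "sigma_b": 0.3, "sigma_obs": 0.1}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((DATA / "truth.json").read_text())
    census = gio.read_census(DATA / "census.csv")
    fec = gio.read_fecundity(DATA / "fecundity.csv")
    cols = gio.read_colonies(DATA / "colonies.csv")
    clim = gio.read_climate(DATA / "climate.csv", DATA / "climate_constants.json")

    spec = ModelSpec(id=truth["spec"],
                     fecundity_terms=(("nsAT", 1), ("nsAT", 2), ("prec", 1)),
                     recruitment_terms=(("SST", 1),))
    y0, y1 = truth["fit_years"]
    data = inf.prepare_data(census, fec, clim, list(cols.colony_id),
                            range(y0, y1 + 1), cols.K_expert.to_numpy(),
                            hpai_statuses=list(cols.hpai_status))

    t0 = time.time()
    settings = inf.MCMCSettings(chains=4, iters=5000, burnin=2000, thin=5,
                                seed=SEED)
    res = inf.run_mcmc(data, spec, DemographicParams(K=data.K_expert), settings)
    summ = inf.summarize(res)
    print(f"sampling took {time.time() - t0:.0f}s "
          f"({settings.chains} chains x {settings.iters} iterations)")

    tab = summ.params.set_index("name")
    print(f"\n{'parameter':14s} {'truth':>8s} {'median':>8s} "
          f"{'lo95':>8s} {'hi95':>8s} {'rhat':>6s}")
    for name, true in TRUTH.items():
        r = tab.loc[name]
        print(f"{name:14s} {true:8.3f} {r['median']:8.3f} "
              f"{r['lo95']:8.3f} {r['hi95']:8.3f} {r['rhat']:6.3f}")
    print(f"\nmax R-hat = {summ.max_rhat:.3f} "
          f"({'converged' if summ.converged else 'NOT converged'} at 1.1)")
    print(f"DIC = {summ.dic:.1f} (Dbar = {summ.dbar:.1f}, pD = {summ.pd_:.1f})")

    summ.params.to_csv(OUT / "posterior_summary.csv", index=False)
    summ.latent.to_csv(OUT / "latent_states.csv", index=False)
    gio.write_draws(res, OUT / "draws.csv")
    gio.write_manifest(OUT, "analysis/02_fit_model", {"model": spec.id},
                       SEED, time.time() - t0,
                       extra={"DIC": summ.dic, "max_rhat": summ.max_rhat})
    print(f"wrote posterior tables to {OUT}/")


if __name__ == "__main__":
    main()
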