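#!/usr/bin/env python
"""Forecast the metapopulation to 2100 under SSP1 and SSP5.

Refits the generating structure (settings and seed as in 02, so the
posterior is identical), pushes each retained draw forward under both
climate scenarios with the 2022 HPAI survival shock, and reports: the
metapopulation trajectory, colony-level sensitivities (% difference in
median size, SSP5 vs SSP1) at 2030/2065/2100, carrying-capacity
dominance switches, and the four-way trajectory classification.
"""

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from gannetpop import inference as inf
from gannetpop import io as gio
from gannetpop.forecast import (REFERENCE_YEARS, classify_all, forecast,
                                sensitivity)
from gannetpop.modelspec import ModelSpec
from gannetpop.params import DemographicParams

DATA = Path("results/data")
OUT = Path("results/forecast")
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((DATA / "truth.json").read_text())
    census = gio.read_census(DATA / "census.csv")
    fec = gio.read_fecundity(DATA / "fecundity.csv")
    cols = gio.read_colonies(DATA / "colonies.csv")
    clim = gio.read_climate(DATA / "climate.csv", DATA / "climate_constants.json")
    y0, y1 = truth["fit_years"]
    spec = ModelSpec(id=truth["spec"],
                     fecundity_terms=(("nsAT", 1), ("nsAT", 2), ("prec", 1)),
                     recruitment_terms=(("SST", 1),))
    data = inf.prepare_data(census, fec, clim, list(cols.colony_id),
                            range(y0, y1 + 1), cols.K_expert.to_numpy(),
                            hpai_statuses=list(cols.hpai_status))

    t0 = time.time()
    settings = inf.MCMCSettings(chains=4, iters=5000, burnin=2000, thin=5,
                                seed=SEED)
    res = inf.run_mcmc(data, spec, DemographicParams(K=data.K_expert), settings)
    fres = forecast(res, clim, list(cols.hpai_status), seed=SEED, n_draws=200)
    print(f"fit + forecast took {time.time() - t0:.0f}s")

    i22 = fres.year_index(2022)
    for scen in ("SSP1", "SSP5"):
        tot = fres.total_median[scen]
        print(f"\n{scen}: metapopulation median {tot[0]:.0f} AOS in "
              f"{fres.years[0]}, {tot[i22 + 1]:.0f} after the 2022 HPAI year, "
              f"{tot[-1]:.0f} in 2100")

    print("\nsensitivity (% difference in median colony size, SSP5 vs SSP1):")
    tabs = []
    for y in REFERENCE_YEARS:
        s = sensitivity(fres, y)
        tabs.append(s)
        vals = ", ".join(f"{c}: {v:+.0f}%" for c, v in
                         zip(s.colony, s.sensitivity_pct))
        print(f"  {y}: {vals}")

    classes = classify_all(fres)
    print("\ntrajectory classes:", classes)
    switches = {}
    for n, colony in enumerate(fres.colonies):
        dom = fres.dominance["SSP5"][:, n]
        flips = np.sum(np.diff(np.sign(dom)) != 0)
        switches[colony] = int(flips)
    print("dominance regime switches under SSP5:", switches)

    fres.to_frame().to_csv(OUT / "forecast.csv", index=False)
    pd.concat(tabs).to_csv(OUT / "sensitivity.csv", index=False)
    pd.DataFrame(sorted(classes.items()),
                 columns=["colony", "trajectory_class"]
                 ).to_csv(OUT / "trajectory_classes.csv", index=False)
    gio.write_manifest(OUT, "analysis/04_forecast_scenarios",
                       {"model": spec.id, "n_draws": 200}, SEED,
                       time.time() - t0)
    print(f"wrote forecast tables to {OUT}/")


if __name__ == "__main__":
    main()
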