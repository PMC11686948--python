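#!/usr/bin/env python
"""Generate the baseline synthetic study and write it under results/data/.

Six colonies on a 48-71 degN latitudinal gradient (about 10 degC of
near-surface air temperature), census and fecundity observations over
1957-2016, and climate series to 2100 that split into SSP1/SSP5 after
2014.  The generating coefficients are the posterior medians of the
published best model, so the system has an interior fecundity optimum
with colonies on both sides of it.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gannetpop import io as gio
from gannetpop.params import COVARIATES
from gannetpop.synthetic import generate_study

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = generate_study(seed=SEED)

    study.census.to_csv(OUT / "census.csv", index=False)
    study.fecundity.to_csv(OUT / "fecundity.csv", index=False)
    study.latent.to_csv(OUT / "latent_true.csv", index=False)
    gio.write_climate(study.climate, OUT / "climate.csv",
                      OUT / "climate_constants.json")
    pd.DataFrame({
        "colony_id": study.colonies, "name": study.colonies,
        "lon": np.linspace(-8, 20, len(study.colonies)),
        "lat": study.latitudes,
        "K_expert": study.params_true.K,
        "hpai_status": [study.hpai_status[c] for c in study.colonies],
    }).to_csv(OUT / "colonies.csv", index=False)

    p = study.params_true
    with open(OUT / "truth.json", "w") as fh:
        json.dump({"alpha0": p.alpha0, "alpha_lin": p.alpha_lin,
                   "alpha_quad": p.alpha_quad, "beta0": p.beta0,
                   "beta_lin": p.beta_lin, "sigma_b": p.sigma_b,
                   "sigma_obs": p.sigma_obs, "K": list(p.K),
                   "spec": study.spec_true.id,
                   "fit_years": [int(study.years[0]), int(study.years[-1])]},
                  fh, indent=1)

    X = study.climate.to_array("hindcast", study.colonies, study.years[:-1])
    z = X[:, :, COVARIATES.index("nsAT")].mean(axis=0)
    x_star = p.alpha_lin["nsAT"] / (2 * p.alpha_quad["nsAT"])
    lat = study.latent_matrix()

    print(f"seed {SEED}: {len(study.colonies)} colonies, "
          f"{study.years[0]}-{study.years[-1]}")
    print(f"census rows: {len(study.census)} "
          f"({len(study.census) / (len(study.colonies) * len(study.years)):.0%} "
          "of colony-years observed)")
    print(f"fecundity rows: {len(study.fecundity)}")
    print(f"mean nsAT z-scores by colony: {np.round(z, 2)} "
          f"(optimum at z = {x_star:.2f}; "
          f"{np.sum(z > x_star)} colonies above it)")
    print(f"latent sizes in {study.years[-1]}: {lat[-1].round(0)}")
    print(f"HPAI statuses: {study.hpai_status}")
    print(f"wrote fixtures to {OUT}/")


if __name__ == "__main__":
    main()
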