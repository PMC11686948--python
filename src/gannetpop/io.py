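"""Validated file I/O, run configuration and manifests.

All artifacts are plain text: CSV tables for data and results, JSON for
standardization constants, generating-truth records and run manifests.
Schemas:

* census:    ``colony_id, year, aos_count``
* fecundity: ``colony_id, year, nests, chicks``
* colonies:  ``colony_id, name, lon, lat, K_expert, hpai_status``
* climate:   ``scenario, colony, year, covariate, value`` (long), with
  z-scoring constants in a sidecar JSON ``{covariate: [mean, sd]}``
* draws:     ``chain, iteration, parameter, value`` (long)

Coordinates are decimal degrees WGS84; years are calendar years.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import ClimateSeries
from .params import COVARIATES, HPAI_STATUSES


class SchemaError(ValueError):
    """A data file violated its schema; message carries row/column context."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def read_census(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["colony_id", "year", "aos_count"], path)
    bad = df.aos_count < 0
    if bad.any():
        raise SchemaError(f"{path}: row {int(df.index[bad][0]) + 2}: negative aos_count")
    return df


def read_fecundity(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["colony_id", "year", "nests", "chicks"], path)
    bad = (df.chicks > df.nests) | (df.chicks < 0) | (df.nests <= 0)
    if bad.any():
        raise SchemaError(f"{path}: row {int(df.index[bad][0]) + 2}: "
                          "chicks must satisfy 0 <= chicks <= nests, nests > 0")
    return df


def read_colonies(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["colony_id", "name", "lon", "lat", "K_expert",
                          "hpai_status"], path)
    bad = ~df.hpai_status.isin(HPAI_STATUSES)
    if bad.any():
        raise SchemaError(f"{path}: row {int(df.index[bad][0]) + 2}: hpai_status "
                          f"must be one of {HPAI_STATUSES}")
    bad = df.K_expert <= 0
    if bad.any():
        raise SchemaError(f"{path}: row {int(df.index[bad][0]) + 2}: K_expert <= 0")
    return df


def read_climate(path, constants_path=None) -> ClimateSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["scenario", "colony", "year", "covariate", "value"], path)
    unknown = set(df.covariate.unique()) - set(COVARIATES)
    if unknown:
        raise SchemaError(f"{path}: unknown covariates {sorted(unknown)}")
    constants = None
    if constants_path is not None:
        with open(constants_path) as fh:
            constants = {k: tuple(v) for k, v in json.load(fh).items()}
    return ClimateSeries(df, constants)


def write_climate(series: ClimateSeries, path, constants_path=None) -> None:
    series.table.to_csv(path, index=False)
    if constants_path is not None and series.constants is not None:
        with open(constants_path, "w") as fh:
            json.dump({k: list(v) for k, v in series.constants.items()}, fh, indent=1)


def write_draws(result, path) -> None:
    """Posterior draws as long CSV (chain, iteration, parameter, value)."""
    rows = []
    for c in range(result.draws.shape[0]):
        for i in range(result.draws.shape[1]):
            for name, v in zip(result.param_names, result.draws[c, i]):
                if name:
                    rows.append((c, i, name, v))
    pd.DataFrame(rows, columns=["chain", "iteration", "parameter", "value"]
                 ).to_csv(path, index=False)


def read_draws(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["chain", "iteration", "parameter", "value"], path)
    return df


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    census: str = ""
    fecundity: str = ""
    climate: str = ""
    climate_constants: str = ""
    colonies: str = ""
    model: str = "m0.00"
    chains: int = 4
    iters: int = 5000
    burnin: int = 2000
    thin: int = 5
    seed: int = 1
    scenario: str = "hindcast"
    fit_years: tuple = (1957, 2016)
    end_year: int = 2100
    outdir: str = "results"
    thresholds: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["fit_years"] = list(self.fit_years)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "fit_years" in d:
            d["fit_years"] = tuple(d["fit_years"])
        return cls(**d)


def write_manifest(outdir, command: str, config: dict, seed: int,
                   runtime_s: float, extra: dict | None = None) -> Path:
    """Record what produced the artifacts in ``outdir``."""
    import gannetpop

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "runtime_s": round(runtime_s, 2),
        "versions": {
            "gannetpop": gannetpop.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return path
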